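"""Core data model: topology, trajectory, oriented frame sets, contact maps.

All coordinates are in Å, times in ps, charges in elementary charge units,
masses in amu.  The pore-axis convention used throughout the package is fixed
by :class:`OrientedFrameSet`: the pore axis is +z, the intracellular side is
at low z and the extracellular side at high z, and the centroid of the
alignment selection sits at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

PROTEIN_RESNAMES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS HSD HSE HSP ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL".split()
)
WATER_RESNAMES = frozenset("SOL HOH WAT TIP3 TIP TP3 SPC T3P".split())
ION_RESNAMES = frozenset("K POT CL CLA NA SOD K+ CL- NA+ MG CA CAL".split())
LIPID_RESNAMES = frozenset("POPC POPE POPS DPPC DOPC DMPC LIP PLC".split())

GROUPS = ("protein", "ion", "water", "lipid", "other")


class TopologyError(ValueError):
    """Raised for inconsistent or incomplete topologies."""


class FormatError(ValueError):
    """Raised when a structure/trajectory file cannot be parsed."""


def group_for_resname(resname: str) -> str:
    """Classify a residue name into one of the coarse atom groups."""
    rn = resname.strip().upper()
    if rn in WATER_RESNAMES:
        return "water"
    if rn in ION_RESNAMES:
        return "ion"
    if rn in LIPID_RESNAMES:
        return "lipid"
    if rn in PROTEIN_RESNAMES:
        return "protein"
    return "other"


@dataclass
class Topology:
    """Per-atom static attributes of a molecular system.

    Atom ids are contiguous from 0; every atom carries exactly one group
    label from :data:`GROUPS` and a partial charge in elementary units
    (0 when no charge table was supplied).
    """

    names: np.ndarray          # str per atom
    elements: np.ndarray       # str per atom
    residue_indices: np.ndarray  # int per atom
    residue_names: np.ndarray  # str per atom
    subunit_ids: np.ndarray    # str per atom (chain / segment)
    charges: np.ndarray        # float, e
    masses: np.ndarray         # float, amu
    groups: np.ndarray         # str per atom, one of GROUPS

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("elements", "residue_indices", "residue_names",
                     "subunit_ids", "charges", "masses", "groups"):
            if len(getattr(self, attr)) != n:
                raise TopologyError(f"{attr} length != atom count {n}")
        if not np.all(np.isfinite(self.charges)):
            raise TopologyError("partial charges must be finite")
        bad = set(np.unique(self.groups)) - set(GROUPS)
        if bad:
            raise TopologyError(f"unknown group labels: {sorted(bad)}")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom_ids(self, group: str | None = None) -> np.ndarray:
        """Ids of all atoms, optionally restricted to one group."""
        ids = np.arange(self.n_atoms)
        if group is None:
            return ids
        return ids[self.groups == group]

    def select_names(self, names: Iterable[str]) -> np.ndarray:
        wanted = set(names)
        return np.array([i for i, nm in enumerate(self.names) if nm in wanted],
                        dtype=int)

    def residues(self, group: str = "protein") -> list[int]:
        """Sorted unique residue indices belonging to ``group``."""
        mask = self.groups == group
        return sorted(set(self.residue_indices[mask].tolist()))


@dataclass
class Trajectory:
    """Frames of coordinates with orthorhombic box lengths and times.

    coordinates: (n_frames, n_atoms, 3) in Å; box: (n_frames, 3) in Å;
    times: (n_frames,) in ps, strictly increasing.
    """

    coordinates: np.ndarray
    box: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        nf = self.coordinates.shape[0]
        if self.box.shape != (nf, 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if self.times.shape != (nf,):
            raise ValueError("times must have shape (n_frames,)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be strictly positive")
        if nf > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def check_against(self, topo: Topology) -> None:
        if self.n_atoms != topo.n_atoms:
            raise TopologyError(
                f"trajectory has {self.n_atoms} atoms, topology {topo.n_atoms}")

    @property
    def duration_ns(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.times[-1] - self.times[0]) / 1000.0


@dataclass
class OrientedFrameSet:
    """A trajectory after rigid-body superposition onto a reference frame.

    Fixes the axis convention for all downstream analyses: pore axis = +z,
    intracellular at low z, extracellular at high z; the alignment-selection
    centroid is at the origin in every frame.
    """

    trajectory: Trajectory
    reference_frame: int
    align_selection: np.ndarray = field(repr=False)

    @property
    def coordinates(self) -> np.ndarray:
        return self.trajectory.coordinates

    @property
    def n_frames(self) -> int:
        return self.trajectory.n_frames


@dataclass
class ContactMap:
    """Trajectory-averaged residue–residue minimum-distance matrix in nm.

    Each entry is the mean over sampled frames of the shortest inter-atomic
    distance between the two residues, with the per-frame distance capped at
    ``truncation_nm`` before averaging.
    """

    residue_labels: list[str]  # "subunit:resid"
    matrix: np.ndarray  # nm, symmetric, zero diagonal
    truncation_nm: float
    n_frames_used: int

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.residue_labels):
            raise ValueError("matrix shape inconsistent with residue list")
        if not np.allclose(m, m.T):
            raise ValueError("contact map must be symmetric")
        if np.any(m < 0) or np.any(m > self.truncation_nm + 1e-12):
            raise ValueError("entries must lie in [0, truncation]")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.residue_labels,
                            columns=self.residue_labels)
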