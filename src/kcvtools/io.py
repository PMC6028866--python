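"""Structure and trajectory IO (PDB / GRO / XTC / DCD / multi-MODEL PDB).

File parsing and writing are delegated to MDAnalysis; this module converts
between MDAnalysis universes and the package's :class:`~kcvtools.model.Topology`
/ :class:`~kcvtools.model.Trajectory` containers, applies the residue
re-wrapping pass (molecules made whole across periodic boundaries, since all
analyses are distance based), joins the optional per-atom charge table, and
enforces the format checks the parsers are lenient about (duplicate atom
serials, alternate locations).
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np

from .model import (FormatError, Topology, TopologyError, Trajectory,
                    group_for_resname)

_DEFAULT_BOX_PAD = 20.0  # Å added around the coordinate extent when a file has no box


def _prescan_pdb(path: Path) -> None:
    """Reject PDB dialects the downstream model cannot represent.

    Duplicate atom serials break the contiguous-id invariant; altloc codes
    other than blank/'A' would silently duplicate atoms.
    """
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("MODEL"):
                seen = {}  # serials restart in each MODEL block
                continue
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line) < 54:
                raise FormatError(f"{path}: line {lineno}: truncated atom record")
            serial = line[6:11].strip()
            altloc = line[16]
            if altloc not in (" ", "A"):
                raise FormatError(
                    f"{path}: line {lineno}: unsupported altloc {altloc!r}")
            if serial in seen:
                raise TopologyError(
                    f"{path}: line {lineno}: duplicate atom serial {serial} "
                    f"(first seen on line {seen[serial]})")
            seen[serial] = lineno


def _load_charge_table(path: Path, n_atoms: int) -> np.ndarray:
    charges = np.zeros(n_atoms)
    with open(path) as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"atom_id", "charge"} <= set(
                reader.fieldnames):
            raise FormatError(
                f"{path}: charge table needs columns atom_id,charge")
        for row in reader:
            idx = int(row["atom_id"])
            if not 0 <= idx < n_atoms:
                raise TopologyError(
                    f"{path}: charge-table atom_id {idx} not in topology "
                    f"(0..{n_atoms - 1})")
            charges[idx] = float(row["charge"])
    return charges


def _universe(path: Path, traj: Path | None = None):
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if traj is None:
                return mda.Universe(str(path))
            return mda.Universe(str(path), str(traj))
    except (TopologyError, FormatError):
        raise
    except Exception as exc:  # parser-specific error zoo
        raise FormatError(f"cannot parse {traj or path}: {exc}") from exc


def _topology_from_universe(u, charge_table: Path | None) -> Topology:
    atoms = u.atoms
    n = len(atoms)
    names = np.array([a.name for a in atoms])
    try:
        elements = np.array([a.element if a.element else a.name[:1]
                             for a in atoms])
    except Exception:
        elements = np.array([nm[:1] for nm in names])
    resnames = np.array([a.resname for a in atoms])
    residx = np.array([a.resid for a in atoms], dtype=int)
    try:
        subunits = np.array([a.chainID or a.segid or "A" for a in atoms])
    except Exception:
        subunits = np.array([getattr(a, "segid", "") or "A" for a in atoms])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            masses = np.array(atoms.masses, dtype=float)
    except Exception:
        masses = np.ones(n)
    groups = np.array([group_for_resname(rn) for rn in resnames])
    charges = (np.zeros(n) if charge_table is None
               else _load_charge_table(Path(charge_table), n))
    return Topology(names=names, elements=elements, residue_indices=residx,
                    residue_names=resnames, subunit_ids=subunits,
                    charges=charges, masses=masses, groups=groups)


def _frames_from_universe(u) -> Trajectory:
    coords, boxes, times = [], [], []
    for i, ts in enumerate(u.trajectory):
        xyz = np.array(ts.positions, dtype=float)
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            box = np.array(ts.dimensions[:3], dtype=float)
        else:
            box = xyz.max(axis=0) - xyz.min(axis=0) + _DEFAULT_BOX_PAD
        t = float(getattr(ts, "time", 0.0) or 0.0)
        coords.append(xyz)
        boxes.append(box)
        times.append(t)
    times = np.asarray(times)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        times = np.arange(len(times), dtype=float)  # formats without timestamps
    return Trajectory(coordinates=np.array(coords), box=np.array(boxes),
                      times=times)


def rewrap_molecules(traj: Trajectory, topo: Topology) -> Trajectory:
    """Make each residue contiguous across periodic boundaries (in place).

    Atoms of a residue are shifted by whole box lengths to lie within half a
    box of the residue's first atom.
    """
    coords = traj.coordinates
    residx = topo.residue_indices
    for res in np.unique(residx):
        ids = np.flatnonzero(residx == res)
        if len(ids) < 2:
            continue
        ref = coords[:, ids[0], None, :]
        box = traj.box[:, None, :]
        delta = coords[:, ids, :] - ref
        coords[:, ids, :] -= np.round(delta / box) * box
    return traj


def read_structure(path, charge_table=None) -> tuple[Topology, Trajectory]:
    """Read a PDB or GRO file into a topology and single-frame trajectory.

    Atoms are grouped by residue-name heuristics (water names -> water,
    K/CL -> ion, lipid names -> lipid, amino acids -> protein).  Charges
    default to 0 unless ``charge_table`` (CSV: atom_id,charge) is given.
    """
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        _prescan_pdb(path)
    u = _universe(path)
    topo = _topology_from_universe(u, charge_table)
    traj = _frames_from_universe(u)
    traj.check_against(topo)
    return topo, rewrap_molecules(traj, topo)


def read_trajectory(top_path, traj_path, charge_table=None
                    ) -> tuple[Topology, Trajectory]:
    """Read a multi-frame trajectory (XTC/DCD/multi-MODEL PDB) with topology."""
    top_path, traj_path = Path(top_path), Path(traj_path)
    if top_path.suffix.lower() == ".pdb":
        _prescan_pdb(top_path)
    u = _universe(top_path, traj_path)
    topo = _topology_from_universe(u, charge_table)
    traj = _frames_from_universe(u)
    traj.check_against(topo)
    return topo, rewrap_molecules(traj, topo)


def write_structure(topo: Topology, traj: Trajectory, path) -> None:
    """Write the trajectory as a (multi-MODEL) PDB file."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    path = Path(path)
    traj.check_against(topo)
    # residue bookkeeping: consecutive (resid, subunit) runs define residues
    res_keys: list[tuple[int, str]] = []
    atom_resindex = np.empty(topo.n_atoms, dtype=int)
    for i in range(topo.n_atoms):
        key = (int(topo.residue_indices[i]), str(topo.subunit_ids[i]))
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        atom_resindex[i] = len(res_keys) - 1
    resids = np.array([k[0] for k in res_keys])
    resnames = []
    seen = -np.ones(len(res_keys), dtype=int)
    for i in range(topo.n_atoms):
        if seen[atom_resindex[i]] < 0:
            seen[atom_resindex[i]] = i
    resnames = np.array([topo.residue_names[i] for i in seen])
    segids = np.array([k[1] for k in res_keys])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(topo.n_atoms, n_residues=len(res_keys),
                               atom_resindex=atom_resindex,
                               residue_segindex=np.arange(len(res_keys)),
                               trajectory=True)
        u.add_TopologyAttr("names", topo.names)
        u.add_TopologyAttr("resids", resids)
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("chainIDs", [s[:1] if s else "A"
                                        for s in topo.subunit_ids])
        u.add_TopologyAttr("elements", topo.elements)
        dims = np.hstack([traj.box, np.full((traj.n_frames, 3), 90.0)])
        u.load_new(traj.coordinates.astype(np.float32), format=MemoryReader,
                   dimensions=dims)
        with mda.Writer(str(path), multiframe=traj.n_frames > 1,
                        n_atoms=topo.n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
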