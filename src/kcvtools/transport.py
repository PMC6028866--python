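"""Binding-site geometry, ion/water site assignment, occupancy f_i,
configuration strings, permeation events, and the inferred current.

A binding site is realized as the z-slab between the mean heights of its two
carbonyl-oxygen planes, intersected with a cylinder of ``radial_cutoff``
around the pore axis.  A tracked particle is *in* site i in a frame iff
mean-z(lower plane) <= z <= mean-z(upper plane) and its radial distance to
the axis is within the cutoff; ties at a slab boundary go to the lower site.
The occupancy of a site is f_i = (Σ over frames and tracked ions of the
in-site indicator) / N frames — it can exceed 1 if two ions co-occupy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import OrientedFrameSet, Topology

ELEMENTARY_CHARGE_C = 1.602176634e-19

FILTER_SITES = ("S0", "S1", "S2", "S3", "S4", "S5")
CONFIG_SITES = ("S1", "S2", "S3", "S4", "S5")  # order used in strings


class SiteGeometryError(ValueError):
    """Raised when binding-site slabs overlap or are inverted."""


@dataclass
class BindingSite:
    """One ion-coordination cage between two carbonyl-oxygen planes.

    ``upper_oxygens`` may be None for the outermost site, in which case the
    slab ceiling is ``upper_offset`` above the lower-plane mean.
    """

    label: str
    lower_oxygens: np.ndarray
    upper_oxygens: np.ndarray | None
    radial_cutoff: float = 3.0
    upper_offset: float | None = None

    def __post_init__(self) -> None:
        self.lower_oxygens = np.asarray(self.lower_oxygens, dtype=int)
        if self.upper_oxygens is not None:
            self.upper_oxygens = np.asarray(self.upper_oxygens, dtype=int)
            both = np.concatenate([self.lower_oxygens, self.upper_oxygens])
            if len(np.unique(both)) != len(both):
                raise SiteGeometryError(
                    f"{self.label}: coordinating oxygens must be distinct")
        elif self.upper_offset is None:
            raise SiteGeometryError(
                f"{self.label}: needs either upper oxygens or an upper offset")

    def bounds(self, coords: np.ndarray) -> tuple[float, float]:
        """(z_lo, z_hi) of the slab in one frame's coordinates."""
        zlo = float(coords[self.lower_oxygens, 2].mean())
        if self.upper_oxygens is not None:
            zhi = float(coords[self.upper_oxygens, 2].mean())
        else:
            zhi = zlo + float(self.upper_offset)
        if zhi <= zlo:
            raise SiteGeometryError(
                f"{self.label}: inverted slab (upper plane below lower)")
        return zlo, zhi


@dataclass
class BindingSiteSet:
    """Ordered S5 (innermost) → S0 site collection plus pore parameters."""

    sites: dict[str, BindingSite]
    cavity_radius: float = 5.0

    def __post_init__(self) -> None:
        order = [s for s in ("S5", "S4", "S3", "S2", "S1", "S0")
                 if s in self.sites]
        self.sites = {k: self.sites[k] for k in order}

    @classmethod
    def from_scaffold(cls, scaffold, radial_cutoff: float = 3.0,
                      cavity_radius: float = 5.0) -> "BindingSiteSet":
        defs = scaffold.site_definitions()
        return cls.from_definitions(defs, radial_cutoff, cavity_radius)

    @classmethod
    def from_definitions(cls, defs: dict, radial_cutoff: float = 3.0,
                         cavity_radius: float = 5.0) -> "BindingSiteSet":
        """Build from the JSON form {"S4": {"lower": [...], "upper": [...]}}."""
        sites = {}
        for label, d in defs.items():
            sites[label] = BindingSite(
                label=label, lower_oxygens=np.array(d["lower"]),
                upper_oxygens=(np.array(d["upper"]) if "upper" in d else None),
                radial_cutoff=radial_cutoff,
                upper_offset=d.get("upper_offset"))
        return cls(sites=sites, cavity_radius=cavity_radius)

    def ordered(self) -> list[BindingSite]:
        return list(self.sites.values())

    def validate_frame(self, coords: np.ndarray) -> list[tuple[str, float, float]]:
        """Check slabs are stacked without interior overlap; return bounds."""
        out = []
        for site in self.ordered():
            out.append((site.label, *site.bounds(coords)))
        for (la, lo_a, hi_a), (lb, lo_b, hi_b) in zip(out, out[1:]):
            if lo_b < hi_a - 1e-6:
                raise SiteGeometryError(
                    f"site slabs {la} and {lb} overlap "
                    f"([{lo_a:.2f},{hi_a:.2f}] vs [{lo_b:.2f},{hi_b:.2f}])")
        return out


@dataclass
class SiteAssignmentSeries:
    """Per-frame, per-particle location label.

    Labels are the site names plus "cavity", "extracellular" and "bulk";
    exactly one label per particle per frame.
    """

    labels: np.ndarray           # (n_frames, n_particles), dtype=object
    particle_ids: np.ndarray     # atom ids of the tracked particles
    times_ps: np.ndarray
    site_labels: tuple[str, ...] = FILTER_SITES

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        frames, pids, labs = [], [], []
        for f in range(self.n_frames):
            for j, pid in enumerate(self.particle_ids):
                frames.append(f)
                pids.append(int(pid))
                labs.append(self.labels[f, j])
        return pd.DataFrame({"frame": frames, "time_ps":
                             np.repeat(self.times_ps, len(self.particle_ids)),
                             "particle_id": pids, "label": labs})


@dataclass
class PermeationEvent:
    particle_id: int
    entry_frame: int
    exit_frame: int
    direction: str  # "outward" | "inward"

    def __post_init__(self) -> None:
        if self.exit_frame <= self.entry_frame:
            raise ValueError("exit_frame must follow entry_frame")


def unwrap_z(z_series: np.ndarray, box_z: np.ndarray) -> np.ndarray:
    """Remove periodic jumps from a per-frame z trace.

    A displacement larger than half the box between consecutive frames is
    treated as a boundary crossing.
    """
    z = np.asarray(z_series, dtype=float).copy()
    dz = np.diff(z)
    bz = np.broadcast_to(np.asarray(box_z, dtype=float), dz.shape
                         if np.ndim(box_z) else (len(dz),))
    shift = -np.cumsum(np.round(dz / bz) * bz)
    z[1:] += shift
    return z


def assign_sites(oriented: OrientedFrameSet, topo: Topology,
                 sites: BindingSiteSet, tracked: Sequence[int]
                 ) -> SiteAssignmentSeries:
    """Label each tracked particle's location in every frame.

    Sites are tested from the innermost (S5) up, so a particle exactly on a
    shared slab boundary is assigned to the lower site.  Below the lowest
    slab and within ``cavity_radius`` of the axis → "cavity"; above the
    topmost slab → "extracellular"; anything else → "bulk".
    """
    tracked = np.asarray(tracked, dtype=int)
    if tracked.size == 0:
        raise ValueError("tracked set must be non-empty")
    groups = topo.groups[tracked]
    names = topo.names[tracked]
    ok = (groups == "ion") | ((groups == "water")
                              & np.char.startswith(names.astype(str), "O"))
    if not np.all(ok):
        raise ValueError("tracked atoms must be ions or water oxygens")

    coords = oriented.coordinates
    n_frames = coords.shape[0]
    labels = np.empty((n_frames, tracked.size), dtype=object)
    for f in range(n_frames):
        frame_bounds = sites.validate_frame(coords[f])
        z_bottom = frame_bounds[0][1]
        z_top = frame_bounds[-1][2]
        xyz = coords[f, tracked]
        r = np.hypot(xyz[:, 0], xyz[:, 1])
        z = xyz[:, 2]
        for j in range(tracked.size):
            lab = None
            for site, (_, zlo, zhi) in zip(sites.ordered(), frame_bounds):
                if zlo <= z[j] <= zhi and r[j] <= site.radial_cutoff:
                    lab = site.label
                    break
            if lab is None:
                if z[j] < z_bottom and r[j] <= sites.cavity_radius:
                    lab = "cavity"
                elif z[j] > z_top:
                    lab = "extracellular"
                else:
                    lab = "bulk"
            labels[f, j] = lab
    return SiteAssignmentSeries(labels=labels, particle_ids=tracked,
                                times_ps=oriented.trajectory.times.copy())


def occupancy(series: SiteAssignmentSeries, site: str) -> float:
    """f_i = (Σ over frames and particles of the in-site indicator) / N."""
    if site not in series.site_labels:
        raise ValueError(f"unknown site label {site!r}")
    n = series.n_frames
    if n < 1:
        raise ValueError("need at least one frame")
    return float((series.labels == site).sum()) / n


def occupancy_table(series: SiteAssignmentSeries) -> pd.DataFrame:
    rows = [{"site": s, "occupancy": occupancy(series, s)}
            for s in series.site_labels]
    return pd.DataFrame(rows)


def configuration_series(ion_series: SiteAssignmentSeries,
                         water_series: SiteAssignmentSeries) -> list[str]:
    """Per-frame filter configuration strings over S1..S5.

    Ion present → the site label; else water present → "W"; else "0".
    Rendered in the conventional outer-to-inner order, e.g. "{W,S2,W,S4,S5}".
    """
    if ion_series.n_frames != water_series.n_frames:
        raise ValueError("ion and water series must share the frame clock")
    out = []
    for f in range(ion_series.n_frames):
        ion_at = set(ion_series.labels[f])
        wat_at = set(water_series.labels[f])
        symbols = []
        for s in CONFIG_SITES:
            if s in ion_at:
                symbols.append(s)
            elif s in wat_at:
                symbols.append("W")
            else:
                symbols.append("0")
        out.append("{" + ",".join(symbols) + "}")
    return out


def count_permeations(series: SiteAssignmentSeries,
                      sites: BindingSiteSet | None = None
                      ) -> list[PermeationEvent]:
    """Full translocation events across the filter, per tracked particle.

    An outward event: the particle's label sequence passes
    cavity → (filter sites) → extracellular without re-entering the cavity in
    between; inward is the mirror.  Events are disjoint in time per particle.
    """
    site_set = set(sites.sites) if sites is not None else set(FILTER_SITES)
    events: list[PermeationEvent] = []
    for j, pid in enumerate(series.particle_ids):
        armed_from: str | None = None   # side last visited: cavity/extracellular
        entry: int | None = None        # frame of first filter-site visit
        for f in range(series.n_frames):
            lab = series.labels[f, j]
            if lab == "cavity":
                if armed_from == "extracellular" and entry is not None:
                    events.append(PermeationEvent(
                        particle_id=int(pid), entry_frame=entry, exit_frame=f,
                        direction="inward"))
                armed_from = "cavity"
                entry = None
            elif lab == "extracellular":
                if armed_from == "cavity" and entry is not None:
                    events.append(PermeationEvent(
                        particle_id=int(pid), entry_frame=entry, exit_frame=f,
                        direction="outward"))
                armed_from = "extracellular"
                entry = None
            elif lab in site_set:
                if armed_from is not None and entry is None:
                    entry = f
            # "bulk" frames neither arm nor cancel a traversal in progress
    return events


def events_to_dataframe(events: Sequence[PermeationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"particle_id": e.particle_id, "entry_frame": e.entry_frame,
          "exit_frame": e.exit_frame, "direction": e.direction}
         for e in events],
        columns=["particle_id", "entry_frame", "exit_frame", "direction"])


def inferred_current(n_events: int, duration_ns: float,
                     charge_per_event: float = 1.0) -> float:
    """Single-channel current in pA implied by counted permeation events.

    I = n · q·e / t; with the conventional one elementary charge per event.
    """
    if duration_ns <= 0:
        raise ValueError("duration must be positive")
    amps = n_events * charge_per_event * ELEMENTARY_CHARGE_C \
        / (duration_ns * 1e-9)
    return amps * 1e12
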