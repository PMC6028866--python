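"""Carbonyl-orientation analysis for the selectivity filter.

Each filter carbonyl is described per frame by two variables: the
(C, Cα, N, O) torsion and the radial distance of the carbonyl oxygen to the
pore axis.  The 2-D point clouds are clustered with DBSCAN on standardized
features (the dihedral treated circularly), clusters are named pore-facing
or helix-facing by the nearer of two reference anchors, and orientation
flips are cross-referenced in time against ion relocation events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .model import OrientedFrameSet, Topology, TopologyError
from .transport import SiteAssignmentSeries

STATES = ("pore_facing", "helix_facing", "noise")
BACKBONE_QUAD = ("C", "CA", "N", "O")


class OrientationTieError(ValueError):
    """Both reference anchors equidistant from a cluster centroid."""


@dataclass
class ReferencePoints:
    """(dihedral deg, radial Å) anchors for the two carbonyl states.

    Real analyses would read these from conductive-state channel structures;
    the packaged defaults are synthetic, matched to the scaffold generator.
    """

    pore_facing: tuple[float, float]
    helix_facing: tuple[float, float]

    def __post_init__(self) -> None:
        if tuple(self.pore_facing) == tuple(self.helix_facing):
            raise ValueError("reference anchors must be distinct")


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
             ) -> np.ndarray:
    """Torsion (degrees, in (−180, 180]) of ordered point quadruples.

    Right-hand-rule sign about the p1→p2 axis (the IUPAC convention, with
    0° = cis); vectorized over leading dimensions and computed in double
    precision via atan2(|b2| b1·(b2×b3), (b1×b2)·(b2×b3)).
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=np.float64)
                      for p in (p0, p1, p2, p3))
    scalar = p0.ndim == 1
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    y = np.linalg.norm(b2, axis=-1) * np.einsum("...i,...i->...", b1, n2)
    x = np.einsum("...i,...i->...", n1, n2)
    out = np.degrees(np.arctan2(y, x))
    out = np.where(out <= -180.0, out + 360.0, out)
    return float(out) if scalar else out


def descriptors(oriented: OrientedFrameSet, topo: Topology,
                residues: Sequence[int], subunits: Sequence[str]
                ) -> pd.DataFrame:
    """Per-frame (dihedral, radial distance) for each (residue, subunit).

    Columns: frame, time_ps, residue, subunit, dihedral_deg, radial_A.
    The radial distance is sqrt(x² + y²) of the carbonyl O in oriented
    coordinates (pore axis = z through the origin).
    """
    coords = oriented.coordinates
    rows = []
    for res in residues:
        for su in subunits:
            sel = {}
            for nm in BACKBONE_QUAD:
                ids = np.flatnonzero((topo.residue_indices == res)
                                     & (topo.subunit_ids == su)
                                     & (topo.names == nm))
                if ids.size != 1:
                    raise TopologyError(
                        f"residue {res} subunit {su}: expected one atom "
                        f"named {nm}, found {ids.size}")
                sel[nm] = ids[0]
            quad = [coords[:, sel[nm]] for nm in BACKBONE_QUAD]
            dih = dihedral(*quad)
            o_xy = coords[:, sel["O"], :2]
            rad = np.hypot(o_xy[:, 0], o_xy[:, 1])
            for f in range(coords.shape[0]):
                rows.append((f, oriented.trajectory.times[f], res, su,
                             dih[f], rad[f]))
    return pd.DataFrame(rows, columns=["frame", "time_ps", "residue",
                                       "subunit", "dihedral_deg", "radial_A"])


def _standardize(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = points.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return points / sd, sd


def cluster_states(points: np.ndarray, eps: float = 0.5,
                   min_samples: int = 10) -> np.ndarray:
    """DBSCAN over (dihedral deg, radial Å) points; −1 marks noise.

    Features are standardized (divided by their standard deviation); the
    dihedral is treated circularly by clustering the points together with
    copies shifted ±360° and folding the labels back, so clusters spanning
    the ±180° seam are not split.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be (n, 2): dihedral_deg, radial_A")
    n = len(points)
    if n < 1:
        raise ValueError("no points to cluster")
    if eps <= 0:
        raise ValueError("eps must be positive (degenerate density radius)")
    _, sd = _standardize(points)
    copies = np.vstack([points + np.array([shift, 0.0])
                        for shift in (-360.0, 0.0, 360.0)]) / sd
    raw = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(copies)

    # fold: the three copies of one point must share a cluster label
    parent: dict[int, int] = {}

    def find(a: int) -> int:
        while parent.setdefault(a, a) != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i in range(n):
        labs = {raw[i], raw[i + n], raw[i + 2 * n]} - {-1}
        labs = sorted(labs)
        for a, b in zip(labs, labs[1:]):
            union(a, b)
    labels = np.full(n, -1, dtype=int)
    remap: dict[int, int] = {}
    for i in range(n):
        cands = [raw[i + k * n] for k in range(3) if raw[i + k * n] != -1]
        if not cands:
            continue
        root = find(cands[0])
        if root not in remap:
            remap[root] = len(remap)
        labels[i] = remap[root]
    return labels


def assign_orientation(labels: np.ndarray, points: np.ndarray,
                       refs: ReferencePoints) -> np.ndarray:
    """Name each cluster by the nearer reference anchor.

    Distances are Euclidean in the same standardized space used for
    clustering, with the dihedral coordinate compared circularly.  Noise
    points keep the state "noise"; an exact tie raises rather than guessing.
    """
    labels = np.asarray(labels)
    points = np.asarray(points, dtype=float)
    _, sd = _standardize(points)

    def dist(a: np.ndarray, anchor: tuple[float, float]) -> float:
        ddi = a[0] - anchor[0]
        ddi = (ddi + 180.0) % 360.0 - 180.0
        return float(np.hypot(ddi / sd[0], (a[1] - anchor[1]) / sd[1]))

    states = np.full(len(points), "noise", dtype=object)
    for lab in sorted(set(labels) - {-1}):
        centroid = points[labels == lab].mean(axis=0)
        d_pore = dist(centroid, refs.pore_facing)
        d_helix = dist(centroid, refs.helix_facing)
        if abs(d_pore - d_helix) < 1e-9:
            raise OrientationTieError(
                f"cluster {lab}: anchors equidistant (d={d_pore:.6g})")
        states[labels == lab] = ("pore_facing" if d_pore < d_helix
                                 else "helix_facing")
    return states


def orientation_series(desc: pd.DataFrame, refs: ReferencePoints,
                       eps: float = 0.5, min_samples: int = 10,
                       pooled: bool = False) -> pd.DataFrame:
    """Cluster descriptors and attach a state column.

    By default each (residue, subunit) pair is clustered independently
    (matching the per-carbonyl presentation of the raw traces); ``pooled``
    clusters all carbonyls together.
    """
    desc = desc.copy()
    desc["state"] = "noise"
    keys = ([(None, None)] if pooled
            else desc[["residue", "subunit"]].drop_duplicates().itertuples(
                index=False, name=None))
    for res, su in keys:
        mask = (np.ones(len(desc), dtype=bool) if res is None
                else ((desc["residue"] == res)
                      & (desc["subunit"] == su)).to_numpy())
        pts = desc.loc[mask, ["dihedral_deg", "radial_A"]].to_numpy()
        labels = cluster_states(pts, eps=eps, min_samples=min_samples)
        desc.loc[mask, "state"] = assign_orientation(labels, pts, refs)
    return desc


def flip_events(orientation: pd.DataFrame) -> pd.DataFrame:
    """State changes per (residue, subunit), noise frames ignored.

    Returns columns: residue, subunit, frame, time_ps, from_state, to_state.
    """
    rows = []
    for (res, su), grp in orientation.groupby(["residue", "subunit"]):
        grp = grp[grp["state"] != "noise"].sort_values("frame")
        prev = None
        for _, rec in grp.iterrows():
            if prev is not None and rec["state"] != prev["state"]:
                rows.append((res, su, int(rec["frame"]), rec["time_ps"],
                             prev["state"], rec["state"]))
            prev = rec
    return pd.DataFrame(rows, columns=["residue", "subunit", "frame",
                                       "time_ps", "from_state", "to_state"])


def relocation_times(series: SiteAssignmentSeries) -> np.ndarray:
    """Times (ps) at which any tracked ion changes its location label."""
    times = []
    for f in range(1, series.n_frames):
        if np.any(series.labels[f] != series.labels[f - 1]):
            times.append(series.times_ps[f])
    return np.asarray(times, dtype=float)


def coincidence(orientation: pd.DataFrame, ion_series: SiteAssignmentSeries,
                window_ns: float) -> pd.DataFrame:
    """For each carbonyl flip, the lag to the nearest ion relocation.

    Columns: residue, subunit, flip_time_ps, nearest_relocation_ps, lag_ns,
    within_window.  Empty inputs yield an empty table.  The summary fraction
    of flips within the window is ``table["within_window"].mean()``.
    """
    flips = flip_events(orientation)
    reloc = relocation_times(ion_series)
    rows = []
    for _, fl in flips.iterrows():
        if reloc.size:
            lags = (reloc - fl["time_ps"]) / 1000.0  # ns
            k = int(np.argmin(np.abs(lags)))
            nearest, lag = reloc[k], float(lags[k])
            within = abs(lag) <= window_ns
        else:
            nearest, lag, within = np.nan, np.nan, False
        rows.append((fl["residue"], fl["subunit"], fl["time_ps"],
                     nearest, lag, within))
    return pd.DataFrame(rows, columns=["residue", "subunit", "flip_time_ps",
                                       "nearest_relocation_ps", "lag_ns",
                                       "within_window"])
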