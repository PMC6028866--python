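"""Seeded synthetic systems emulating every input of the analysis pipeline.

Nothing here aims at physical realism: these are deterministic geometric
fixtures with planted ground truth.

* a four-fold selectivity-filter scaffold whose backbone carbonyl oxygens
  form square cages bounding the ion binding sites S0–S5,
* scripted ion/water trajectories hopping between sites with Gaussian jitter,
* a parallel-plate charge system imposing a known transmembrane voltage drop,
* a toy bilayer with one lipid planted to bind a chosen residue,
* planted 2-D Gaussian blobs for the carbonyl-orientation clusterer.

All generators are pure functions of (spec, seed): identical inputs give
bitwise-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .electrostatics import ChargeSystem, E_PER_A_IN_MV
from .model import Topology, Trajectory

SITE_LABELS = ("S0", "S1", "S2", "S3", "S4", "S5")
FILTER_RESNAMES = ("THR", "VAL", "GLY", "PHE", "GLY", "TYR")  # one per plane
SPECIAL_DESTINATIONS = ("cavity", "extracellular", "bulk")


class ScheduleConflictError(ValueError):
    """Two particles scheduled into the same binding site at the same frame."""


# ---------------------------------------------------------------------------
# filter scaffold
# ---------------------------------------------------------------------------

def _default_planes() -> np.ndarray:
    # six carbonyl-oxygen planes, 3.1 Å apart, centered on z = 0
    z = 3.1 * np.arange(6)
    return z - z.mean()


@dataclass
class ScaffoldSpec:
    """Geometry of the synthetic filter scaffold.

    ``site_plane_z`` lists the six oxygen-plane heights (Å, ascending);
    consecutive planes bound S5 (lowest) through S1, and S0 extends
    ``s0_upper_offset`` above the top plane.  ``cage_radius`` is the distance
    of each pore-facing carbonyl oxygen from the pore axis.
    """

    n_subunits: int = 4
    site_plane_z: np.ndarray = field(default_factory=_default_planes)
    cage_radius: float = 1.4
    s0_upper_offset: float = 3.1
    ca_radius: float = 4.0          # Cα ring radius, Å
    flip_angle_deg: float = 120.0   # O rotation about the Cα–N axis when flipped

    def __post_init__(self) -> None:
        self.site_plane_z = np.asarray(self.site_plane_z, dtype=float)
        if len(self.site_plane_z) != 6:
            raise ValueError("site_plane_z must list six plane heights")
        if np.any(np.diff(self.site_plane_z) <= 0):
            raise ValueError("site_plane_z must be strictly increasing")
        if self.cage_radius <= 0:
            raise ValueError("cage_radius must be positive")
        if self.n_subunits < 3:
            raise ValueError("need at least three subunits")


@dataclass
class FilterScaffold:
    """A built scaffold: topology, one frame, and site/flip bookkeeping."""

    spec: ScaffoldSpec
    topology: Topology
    trajectory: Trajectory  # single frame
    site_bounds: dict[str, tuple[float, float]]
    plane_oxygen_ids: list[np.ndarray]   # per plane, the 4 carbonyl O atom ids
    oxygen_positions: dict[tuple[int, str], dict[str, np.ndarray]]
    # (residue_index, subunit) -> {"pore_facing": xyz, "helix_facing": xyz}
    residue_indices: list[int]
    subunits: list[str]

    def site_definitions(self) -> dict[str, dict]:
        """JSON-ready binding-site definitions (S0 uses a z-offset ceiling)."""
        planes = self.plane_oxygen_ids
        out: dict[str, dict] = {}
        for k in range(5):  # S5..S1 between planes k and k+1
            label = f"S{5 - k}"
            out[label] = {"lower": planes[k].tolist(),
                          "upper": planes[k + 1].tolist()}
        out["S0"] = {"lower": planes[5].tolist(),
                     "upper_offset": self.spec.s0_upper_offset}
        return out

    def site_center_z(self, label: str) -> float:
        zlo, zhi = self.site_bounds[label]
        return 0.5 * (zlo + zhi)


def _rotate_about(vec: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    return (vec * c + np.cross(axis, vec) * s
            + axis * np.dot(axis, vec) * (1 - c))


def make_filter_scaffold(spec: ScaffoldSpec | None = None) -> FilterScaffold:
    """Build the four-fold carbonyl-cage scaffold.

    One residue per oxygen plane and per subunit, each with atoms
    (C, Cα, N, O); the O of every residue sits ``cage_radius`` from the pore
    axis at its plane height (pore-facing state).  A helix-facing alternative
    O position, obtained by rotating the O about the Cα–N axis by
    ``flip_angle_deg``, is stored for flip scripting.
    """
    spec = spec or ScaffoldSpec()
    planes = spec.site_plane_z
    names, resnames, resids, subunits, coords = [], [], [], [], []
    plane_oxy: list[list[int]] = [[] for _ in planes]
    oxy_positions: dict[tuple[int, str], dict[str, np.ndarray]] = {}

    atom_id = 0
    residue_indices = [63 + p for p in range(len(planes))]
    subunit_labels = [chr(ord("A") + s) for s in range(spec.n_subunits)]
    for s, su in enumerate(subunit_labels):
        theta = 2 * np.pi * s / spec.n_subunits
        r_hat = np.array([np.cos(theta), np.sin(theta), 0.0])
        t_hat = np.array([-np.sin(theta), np.cos(theta), 0.0])
        z_hat = np.array([0.0, 0.0, 1.0])
        for p, zp in enumerate(planes):
            ca = spec.ca_radius * r_hat + zp * z_hat
            n = ca + 1.45 * t_hat
            c = ca + 1.52 * (0.5 * r_hat + 0.866 * z_hat)
            o_pore = spec.cage_radius * r_hat + zp * z_hat
            axis = n - ca
            o_helix = n + _rotate_about(o_pore - n, axis,
                                        np.deg2rad(spec.flip_angle_deg))
            for nm, xyz in (("C", c), ("CA", ca), ("N", n), ("O", o_pore)):
                names.append(nm)
                resnames.append(FILTER_RESNAMES[p])
                resids.append(residue_indices[p])
                subunits.append(su)
                coords.append(xyz)
                if nm == "O":
                    plane_oxy[p].append(atom_id)
                atom_id += 1
            oxy_positions[(residue_indices[p], su)] = {
                "pore_facing": o_pore, "helix_facing": o_helix}

    coords = np.array(coords)
    n_atoms = len(names)
    topo = Topology(
        names=np.array(names), elements=np.array([nm[0] for nm in names]),
        residue_indices=np.array(resids), residue_names=np.array(resnames),
        subunit_ids=np.array(subunits), charges=np.zeros(n_atoms),
        masses=np.full(n_atoms, 12.0),
        groups=np.array(["protein"] * n_atoms))

    span = planes[-1] - planes[0]
    box = np.array([[40.0, 40.0, span + 40.0]])
    traj = Trajectory(coordinates=coords[None], box=box, times=np.array([0.0]))

    bounds: dict[str, tuple[float, float]] = {}
    for k in range(5):
        bounds[f"S{5 - k}"] = (float(planes[k]), float(planes[k + 1]))
    bounds["S0"] = (float(planes[5]), float(planes[5] + spec.s0_upper_offset))

    return FilterScaffold(
        spec=spec, topology=topo, trajectory=traj, site_bounds=bounds,
        plane_oxygen_ids=[np.array(p) for p in plane_oxy],
        oxygen_positions=oxy_positions, residue_indices=residue_indices,
        subunits=subunit_labels)


# ---------------------------------------------------------------------------
# scripted hop trajectories
# ---------------------------------------------------------------------------

@dataclass
class HopSchedule:
    """Scripted particle itinerary over a scaffold.

    ``particles`` lists kinds ("ion" or "water"); ``moves`` are
    (frame, particle_index, destination) with destination a site label,
    "cavity", "extracellular" or "bulk".  Every particle needs a move at
    frame 0 (its starting position).  Hops are instantaneous.
    """

    particles: list[str]
    moves: list[tuple[int, int, str]]
    jitter_sd: float = 0.0
    seed: int = 0

    def validate(self, n_frames: int) -> None:
        valid = set(SITE_LABELS) | set(SPECIAL_DESTINATIONS)
        started = set()
        for frame, pid, dest in self.moves:
            if not 0 <= frame < n_frames:
                raise ValueError(f"move frame {frame} outside trajectory")
            if not 0 <= pid < len(self.particles):
                raise ValueError(f"unknown particle {pid}")
            if dest not in valid:
                raise ValueError(f"invalid destination {dest!r}")
            if frame == 0:
                started.add(pid)
        missing = set(range(len(self.particles))) - started
        if missing:
            raise ValueError(f"particles without a frame-0 position: {missing}")

    def itinerary(self, n_frames: int) -> np.ndarray:
        """(n_frames, n_particles) array of destination labels."""
        self.validate(n_frames)
        dest = np.empty((n_frames, len(self.particles)), dtype=object)
        per_particle: dict[int, list[tuple[int, str]]] = {
            i: [] for i in range(len(self.particles))}
        for frame, pid, d in sorted(self.moves):
            per_particle[pid].append((frame, d))
        for pid, stops in per_particle.items():
            for (f0, d), nxt in zip(stops, stops[1:] + [(n_frames, None)]):
                dest[f0:nxt[0], pid] = d
        # no two particles may share one binding site in any frame
        for f in range(n_frames):
            seen: dict[str, int] = {}
            for pid in range(len(self.particles)):
                d = dest[f, pid]
                if d in SITE_LABELS:
                    if d in seen:
                        raise ScheduleConflictError(
                            f"frame {f}: particles {seen[d]} and {pid} both "
                            f"scheduled at {d}")
                    seen[d] = pid
        return dest


def _destination_position(scaffold: FilterScaffold, dest: str) -> np.ndarray:
    if dest in SITE_LABELS:
        return np.array([0.0, 0.0, scaffold.site_center_z(dest)])
    z_bottom = scaffold.site_bounds["S5"][0]
    z_top = scaffold.site_bounds["S0"][1]
    if dest == "cavity":
        return np.array([0.0, 0.0, z_bottom - 6.0])
    if dest == "extracellular":
        return np.array([0.0, 0.0, z_top + 5.0])
    if dest == "bulk":
        mid = 0.5 * (z_bottom + z_top)
        return np.array([scaffold.spec.ca_radius + 12.0, 0.0, mid])
    raise ValueError(dest)


def script_trajectory(scaffold: FilterScaffold, schedule: HopSchedule,
                      n_frames: int, dt_ps: float = 100.0,
                      flips: Sequence[tuple[int, int, str, str]] = (),
                      ) -> tuple[Topology, Trajectory]:
    """Realize a hop schedule as a full trajectory over the scaffold.

    Tracked particles sit at their current destination's cage center plus
    isotropic Gaussian jitter of sd ``schedule.jitter_sd`` (exact positions
    when the sd is 0).  ``flips`` optionally toggles carbonyl orientations:
    (frame, residue_index, subunit, state) with state "pore_facing" or
    "helix_facing"; states persist until the next entry.
    """
    dest = schedule.itinerary(n_frames)
    rng = np.random.default_rng(schedule.seed)
    prot = scaffold.topology
    npart = len(schedule.particles)

    names = list(prot.names)
    resnames = list(prot.residue_names)
    resids = list(prot.residue_indices)
    subunits = list(prot.subunit_ids)
    groups = list(prot.groups)
    next_resid = max(prot.residue_indices) + 1
    for i, kind in enumerate(schedule.particles):
        if kind == "ion":
            names.append("K")
            resnames.append("K")
            groups.append("ion")
        elif kind == "water":
            names.append("OW")
            resnames.append("SOL")
            groups.append("water")
        else:
            raise ValueError(f"unknown particle kind {kind!r}")
        resids.append(next_resid + i)
        subunits.append("X")
    n_atoms = len(names)
    topo = Topology(
        names=np.array(names), elements=np.array([nm[0] for nm in names]),
        residue_indices=np.array(resids), residue_names=np.array(resnames),
        subunit_ids=np.array(subunits), charges=np.zeros(n_atoms),
        masses=np.full(n_atoms, 12.0), groups=np.array(groups))

    base = scaffold.trajectory.coordinates[0]
    coords = np.empty((n_frames, n_atoms, 3))
    coords[:, :prot.n_atoms] = base

    # carbonyl flips: persistent per (residue, subunit) state switches
    o_index = {(int(prot.residue_indices[i]), str(prot.subunit_ids[i])): i
               for i in range(prot.n_atoms) if prot.names[i] == "O"}
    state: dict[tuple[int, str], str] = {}
    flips_by_frame: dict[int, list] = {}
    for frame, resid, su, st in flips:
        flips_by_frame.setdefault(frame, []).append((resid, su, st))
    for f in range(n_frames):
        for resid, su, st in flips_by_frame.get(f, []):
            state[(resid, su)] = st
        for key, st in state.items():
            coords[f, o_index[key]] = scaffold.oxygen_positions[key][st]

    jitter = (rng.normal(0.0, schedule.jitter_sd, size=(n_frames, npart, 3))
              if schedule.jitter_sd > 0 else np.zeros((n_frames, npart, 3)))
    for f in range(n_frames):
        for p in range(npart):
            coords[f, prot.n_atoms + p] = (
                _destination_position(scaffold, dest[f, p]) + jitter[f, p])

    box = np.repeat(scaffold.trajectory.box, n_frames, axis=0)
    times = dt_ps * np.arange(n_frames)
    return topo, Trajectory(coordinates=coords, box=box, times=times)


def conduction_cycle_schedule(seed: int = 0, dwell: int = 10,
                              jitter_sd: float = 0.0) -> tuple[HopSchedule, int, list[str]]:
    """Schedule reproducing a single-file K+ conduction cycle.

    Plants the canonical sequence of filter configurations
    {W,S2,W,S4,S5} -> {W,W,W,S4,S5} -> {W,W,S3,0,S5} -> {W,W,S3,S4,W} ->
    {W,S2,0,S4,W} -> {W,S2,0,S4,S5} -> {S1,0,S3,0,S5} -> {W,W,S3,0,S5},
    each configuration held for ``dwell`` frames.  Returns the schedule, the
    number of frames, and the expected configuration string per epoch.
    """
    # particles: ions A,B,C,D then waters w1..w6
    kinds = ["ion"] * 4 + ["water"] * 6
    A, B, C, D, w1, w2, w3, w4, w5, w6 = range(10)
    epochs = [
        # epoch start states are encoded as moves at the epoch's first frame
        {A: "S2", B: "S4", C: "S5", D: "cavity", w1: "S1", w2: "S3",
         w3: "extracellular", w4: "cavity", w5: "extracellular",
         w6: "bulk"},
        {A: "extracellular", w3: "S2"},
        {B: "S3", w2: "extracellular"},
        {C: "S4", w4: "S5"},
        {B: "S2", w3: "extracellular"},
        {D: "S5", w4: "cavity"},
        {B: "S1", C: "S3", w1: "extracellular"},
        {B: "extracellular", w5: "S1", w6: "S2"},
    ]
    expected = ["{W,S2,W,S4,S5}", "{W,W,W,S4,S5}", "{W,W,S3,0,S5}",
                "{W,W,S3,S4,W}", "{W,S2,0,S4,W}", "{W,S2,0,S4,S5}",
                "{S1,0,S3,0,S5}", "{W,W,S3,0,S5}"]
    moves = []
    for e, changes in enumerate(epochs):
        for pid, d in changes.items():
            moves.append((e * dwell, pid, d))
    n_frames = dwell * len(epochs)
    return (HopSchedule(particles=kinds, moves=moves, jitter_sd=jitter_sd,
                        seed=seed), n_frames, expected)


def traversal_schedule(n_ions: int, n_frames: int, seed: int = 0,
                       jitter_sd: float = 0.0) -> tuple[HopSchedule, int]:
    """Plant ``n_ions`` full inward->outward traversals; returns the planted
    outward event count (== n_ions)."""
    ladder = ["S5", "S4", "S3", "S2", "S1", "extracellular"]
    moves = [(0, i, "cavity") for i in range(n_ions)]
    per_ion = n_frames // max(n_ions, 1)
    if per_ion < len(ladder) + 1:
        raise ValueError("not enough frames to script all traversals")
    for i in range(n_ions):
        start = i * per_ion + 1  # leave >= 1 frame in the cavity first
        steps = np.linspace(start, start + per_ion - 2,
                            len(ladder)).round().astype(int)
        steps = np.maximum.accumulate(steps + np.arange(len(ladder)) * 0)
        prev = start - 1
        for f, d in zip(steps, ladder):
            f = int(max(f, prev + 1))
            moves.append((f, i, d))
            prev = f
    return (HopSchedule(particles=["ion"] * n_ions, moves=moves,
                        jitter_sd=jitter_sd, seed=seed), n_ions)


# ---------------------------------------------------------------------------
# parallel-plate capacitor
# ---------------------------------------------------------------------------

def capacitor_surface_density(target_drop_mV: float, z1: float, z2: float
                              ) -> float:
    """Surface charge density (e/Å²) of the *upper* plate giving the drop.

    With plates -s at z1 and +s at z2 (z1 < z2), the periodic field between
    the plates is E_z = -4*pi*s and the analytic drop is
    Phi(z2) - Phi(z1) = 4*pi*s*(z2 - z1).
    """
    drop_internal = target_drop_mV / E_PER_A_IN_MV  # e/Å
    return drop_internal / (4 * np.pi * (z2 - z1))


def make_plate_capacitor(box: Sequence[float], slab_bounds: tuple[float, float],
                         target_drop_mV: float = 500.0,
                         plane_spacing: float = 1.5,
                         return_layer_half_width: float | None = None,
                         ) -> tuple[ChargeSystem, ChargeSystem]:
    """Reference (zero-charge) and charged parallel-plate systems.

    The charged system holds two uniform square lattices of point charges at
    z1 and z2 whose surface densities ±s are chosen so the analytic
    potential drop Φ(z2) − Φ(z1) equals ``target_drop_mV``.  Because the box
    is periodic, the loop integral of the field must vanish, so a bare plate
    pair would force a compensating ramp through the bulk; an electrode-like
    return double layer straddling the z boundary (plates at ±ε, opposite
    signs) takes up that return drop instead, leaving both bulk regions
    field-free — which is what the electrolyte does in a real membrane
    simulation.
    """
    box = np.asarray(box, dtype=float)
    z1, z2 = slab_bounds
    if not 0 < z1 < z2 < box[2]:
        raise ValueError("slab bounds must satisfy 0 < z1 < z2 < box_z")
    if target_drop_mV == 0:
        raise ValueError("target_drop must be nonzero (degenerate normalization)")
    eps = (plane_spacing if return_layer_half_width is None
           else return_layer_half_width)
    s_mem = capacitor_surface_density(target_drop_mV, z1, z2)
    s_ret = capacitor_surface_density(target_drop_mV, -eps, eps)
    nx = max(2, int(round(box[0] / plane_spacing)))
    ny = max(2, int(round(box[1] / plane_spacing)))
    dx, dy = box[0] / nx, box[1] / ny
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    area = dx * dy
    positions, charges = [], []
    for z, s in ((z1, -s_mem), (z2, +s_mem),
                 (eps, -s_ret), (box[2] - eps, +s_ret)):
        pts = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, z)])
        positions.append(pts)
        charges.append(np.full(X.size, s * area))
    charged = ChargeSystem(positions=np.vstack(positions),
                           charges=np.concatenate(charges), box=box)
    reference = ChargeSystem(positions=np.zeros((0, 3)),
                             charges=np.zeros(0), box=box)
    return reference, charged


# ---------------------------------------------------------------------------
# toy bilayer
# ---------------------------------------------------------------------------

@dataclass
class ToyBilayer:
    topology: Topology
    trajectory: Trajectory
    target_residue: int          # residue index the binder lipid sticks to
    binder_lipid_resid: int
    bound_fraction: float        # planted fraction of frames in contact
    target_position: np.ndarray


def make_toy_bilayer(n_lipids: int = 12, binder: bool = True, seed: int = 0,
                     n_frames: int = 100, bound_fraction: float = 0.96,
                     ) -> ToyBilayer:
    """Pseudo-protein column plus jittering 3-atom pseudo-lipids in a slab.

    If ``binder`` is set, lipid 0's head atom is held within 1 Å of the
    target residue's atom in ``bound_fraction`` of the frames (planted ground
    truth for occupancy-map and contact analyses); the other lipids wander
    with a large jitter so none of their voxels accumulate high occupancy.
    """
    rng = np.random.default_rng(seed)
    n_res = 8
    prot_pos = np.column_stack([np.zeros(n_res), np.zeros(n_res),
                                4.0 * np.arange(n_res) - 14.0])
    target_res = 4
    target_pos = prot_pos[target_res - 1]

    names = ["CA"] * n_res
    resnames = ["ALA"] * n_res
    resids = list(range(1, n_res + 1))
    groups = ["protein"] * n_res
    subunits = ["A"] * n_res

    lipid_heads = []
    for i in range(n_lipids):
        ang = 2 * np.pi * i / max(n_lipids, 1)
        lipid_heads.append(np.array([12.0 * np.cos(ang), 12.0 * np.sin(ang),
                                     float(rng.uniform(-6, 6))]))
    binder_resid = n_res + 1
    for i in range(n_lipids):
        for j, nm in enumerate(("P", "C2", "C3")):
            names.append(nm)
            resnames.append("LIP")
            resids.append(n_res + 1 + i)
            groups.append("lipid")
            subunits.append("L")

    n_atoms = len(names)
    topo = Topology(
        names=np.array(names), elements=np.array([nm[0] for nm in names]),
        residue_indices=np.array(resids), residue_names=np.array(resnames),
        subunit_ids=np.array(subunits), charges=np.zeros(n_atoms),
        masses=np.full(n_atoms, 12.0), groups=np.array(groups))

    n_bound = int(round(bound_fraction * n_frames))
    bound_frames = np.zeros(n_frames, dtype=bool)
    bound_frames[rng.permutation(n_frames)[:n_bound]] = True

    coords = np.empty((n_frames, n_atoms, 3))
    coords[:, :n_res] = prot_pos
    tail_offsets = np.array([[0.0, 0.0, -3.0], [0.0, 0.0, -6.0]])
    for f in range(n_frames):
        a = n_res
        for i in range(n_lipids):
            if binder and i == 0:
                if bound_frames[f]:
                    direction = rng.normal(size=3)
                    direction /= np.linalg.norm(direction)
                    head = target_pos + direction * rng.uniform(0.2, 0.9)
                else:
                    head = target_pos + np.array([6.0, 0.0, 0.0]) \
                        + rng.normal(0, 1.0, 3)
            else:
                head = lipid_heads[i] + rng.normal(0, 4.0, 3)
            coords[f, a] = head
            coords[f, a + 1:a + 3] = head + tail_offsets \
                + rng.normal(0, 3.0, (2, 3))
            a += 3

    box = np.tile(np.array([60.0, 60.0, 60.0]), (n_frames, 1))
    traj = Trajectory(coordinates=coords, box=box,
                      times=1000.0 * np.arange(n_frames))
    return ToyBilayer(topology=topo, trajectory=traj,
                      target_residue=target_res,
                      binder_lipid_resid=binder_resid,
                      bound_fraction=n_bound / n_frames,
                      target_position=target_pos)


# ---------------------------------------------------------------------------
# planted clusters
# ---------------------------------------------------------------------------

def make_planted_clusters(n_per_cluster: int,
                          centers: Sequence[tuple[float, float]],
                          sd: float, seed: int = 0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded Gaussian blobs in (dihedral deg, radial Å) space."""
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for k, c in enumerate(centers):
        pts.append(rng.normal(loc=c, scale=sd, size=(n_per_cluster, 2)))
        labels.append(np.full(n_per_cluster, k))
    return np.vstack(pts), np.concatenate(labels)


def ground_truth_json(obj, path) -> None:
    """Write planted ground truth (schedules, labels, drops) as JSON."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if hasattr(o, "__dict__"):
            return {k: v for k, v in o.__dict__.items()}
        raise TypeError(type(o))
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=default)
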