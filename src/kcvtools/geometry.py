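"""Frame superposition, pore-axis orientation, RMSD, and the contact map."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .model import ContactMap, OrientedFrameSet, Topology, Trajectory


class DegenerateFitError(ValueError):
    """Alignment selection does not determine a rigid fit."""


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Largest-variance direction of a point cloud (unit vector)."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    # resolve the eigenvector sign: keep the hemisphere closest to +z
    if axis[2] < 0 or (axis[2] == 0 and axis[0] < 0):
        axis = -axis
    return axis


def _axis_to_z_rotation(axis: np.ndarray) -> Rotation:
    """Minimal rotation mapping ``axis`` onto +z."""
    z = np.array([0.0, 0.0, 1.0])
    cross = np.cross(axis, z)
    s = np.linalg.norm(cross)
    c = float(np.dot(axis, z))
    if s < 1e-12:
        if c > 0:
            return Rotation.identity()
        return Rotation.from_rotvec(np.pi * np.array([1.0, 0.0, 0.0]))
    angle = np.arctan2(s, c)
    return Rotation.from_rotvec(angle * cross / s)


def kabsch(mobile: np.ndarray, target: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rigid fit of ``mobile`` onto ``target`` (both centered here).

    Returns (rotation matrix, translation) such that
    ``mobile @ R.T + t ≈ target`` in the least-squares sense.
    """
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    R = rot.as_matrix()
    t = tc - mc @ R.T
    return R, t


def orient_frames(traj: Trajectory, topo: Topology,
                  align_selection: np.ndarray,
                  reference: int = 0) -> OrientedFrameSet:
    """Superpose every frame onto ``reference`` and map the pore axis to +z.

    The principal axis of the alignment selection in the reference frame
    defines the pore axis; after orientation the selection centroid sits at
    the origin in every frame.  Intracellular low z / extracellular high z is
    a package-wide convention inherited by all axis-referenced analyses.
    """
    sel = np.asarray(align_selection, dtype=int)
    if sel.size == 0:
        raise ValueError("align_selection must be non-empty")
    if not 0 <= reference < traj.n_frames:
        raise ValueError("reference frame out of range")
    traj.check_against(topo)

    ref_sel = traj.coordinates[reference, sel]
    centered = ref_sel - ref_sel.mean(axis=0)
    if sel.size < 3 or np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateFitError(
            "alignment selection needs >= 3 non-collinear atoms")

    Rz = _axis_to_z_rotation(_principal_axis(ref_sel)).as_matrix()
    target = centered @ Rz.T  # oriented reference selection, centroid at origin

    out = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        R, t = kabsch(traj.coordinates[f, sel], target)
        out[f] = traj.coordinates[f] @ R.T + t
    oriented = Trajectory(coordinates=out, box=traj.box.copy(),
                          times=traj.times.copy())
    return OrientedFrameSet(trajectory=oriented, reference_frame=reference,
                            align_selection=sel)


def rmsd_series(oriented: OrientedFrameSet, selection: np.ndarray
                ) -> np.ndarray:
    """Per-frame RMSD (Å) of ``selection`` against the reference frame.

    Frames are already superposed, so no further fitting is done; the series
    is zero at the reference frame by construction.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("selection must be non-empty")
    coords = oriented.coordinates[:, sel]
    ref = coords[oriented.reference_frame]
    diff = coords - ref
    return np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))


def contact_map(oriented: OrientedFrameSet, topo: Topology,
                n_samples: int = 370, truncation: float = 1.5) -> ContactMap:
    """Residue contact map: trajectory mean of minimum inter-atomic distance.

    ``truncation`` is in nm; each frame's distance is capped at the
    truncation before averaging, so entries lie in [0, truncation].
    """
    n_frames = oriented.n_frames
    n_samples = min(n_samples, n_frames)
    if n_samples < 1:
        raise ValueError("need at least one frame")
    prot = topo.groups == "protein"
    keys = sorted({(str(topo.subunit_ids[i]), int(topo.residue_indices[i]))
                   for i in np.flatnonzero(prot)})
    if len(keys) < 2:
        raise ValueError("need at least two protein residues")
    frame_ids = np.unique(np.linspace(0, n_frames - 1, n_samples).round()
                          .astype(int))
    atom_ids = [np.flatnonzero(prot & (topo.subunit_ids == su)
                               & (topo.residue_indices == r))
                for su, r in keys]
    nres = len(keys)
    acc = np.zeros((nres, nres))
    for f in frame_ids:
        xyz = oriented.coordinates[f]
        for i in range(nres):
            for j in range(i + 1, nres):
                d_nm = cdist(xyz[atom_ids[i]], xyz[atom_ids[j]]).min() / 10.0
                acc[i, j] += min(d_nm, truncation)
    acc = (acc + acc.T) / len(frame_ids)
    labels = [f"{su}:{r}" for su, r in keys]
    return ContactMap(residue_labels=labels, matrix=acc,
                      truncation_nm=truncation, n_frames_used=len(frame_ids))
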