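"""Grid electrostatics: charge spreading, periodic Poisson solve, the
electrical-distance profile δ(z), and the gating charge Q.

The Poisson equation is solved in Gaussian-style reduced units
(∇²Φ = −4π ρ with charge in e and length in Å, so Φ comes out in e/Å) on a
periodic grid by a spectral method; potentials are converted to mV via
1 e/Å = 14 399.645 mV.  The k = 0 mode of the density is dropped, which is
equivalent to a uniform neutralizing background and fixes the mean-zero
gauge.

Point charges are spread with cloud-in-cell (trilinear) assignment followed
by a reciprocal-space Gaussian attenuation; the effective Gaussian width is
clamped to at least half the grid spacing so the density stays representable
on the grid (the clamp is recorded in the field metadata).

The electrical distance δ(z) is the fraction of the applied transmembrane
voltage dropped up to height z: the cylinder-averaged difference between the
potentials with and without applied voltage, anchored to 0 at the
intracellular bulk and normalized by the measured bulk-to-bulk drop, so
δ = 1 at the extracellular bulk by construction.  The gating charge of a
rearrangement λ1 → λ2 is Q = Σ_i q_i [δ(z_i^λ2) − δ(z_i^λ1)].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: conversion factor: potential of 1 e at 1 Å in vacuum, in mV (e²/4πε₀)
E_PER_A_IN_MV = 14399.645


class DegenerateVoltageError(ValueError):
    """Bulk-to-bulk potential difference too small to normalize by."""


@dataclass
class GridSpec:
    """Regular periodic grid: origin (Å), per-axis spacing (Å), dims."""

    origin: np.ndarray
    spacing: np.ndarray
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.dims = tuple(int(d) for d in self.dims)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if any(d < 4 for d in self.dims):
            raise ValueError("grid needs at least 4 points per axis")

    @classmethod
    def from_box(cls, box: Sequence[float], spacing: float = 1.5,
                 origin: Sequence[float] = (0.0, 0.0, 0.0)) -> "GridSpec":
        box = np.asarray(box, dtype=float)
        dims = tuple(max(4, int(round(b / spacing))) for b in box)
        return cls(origin=np.asarray(origin), spacing=box / np.array(dims),
                   dims=dims)

    @property
    def box(self) -> np.ndarray:
        return self.spacing * np.array(self.dims)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])


@dataclass
class ChargeSystem:
    """Point charges (e) at positions (Å) in an orthorhombic periodic box."""

    positions: np.ndarray
    charges: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        self.box = np.asarray(self.box, dtype=float)
        if len(self.positions) != len(self.charges):
            raise ValueError("positions and charges length mismatch")
        if not (np.all(np.isfinite(self.positions))
                and np.all(np.isfinite(self.charges))):
            raise ValueError("positions and charges must be finite")

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())


@dataclass
class ScalarField:
    """Per-voxel values on a GridSpec, tagged with a unit."""

    grid: GridSpec
    values: np.ndarray
    unit: str  # "e_per_A3", "e_per_A", or "mV"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            raise ValueError("value array does not match grid dims")

    def integral(self) -> float:
        return float(self.values.sum() * self.grid.voxel_volume)

    def to_millivolts(self) -> "ScalarField":
        if self.unit == "mV":
            return self
        if self.unit != "e_per_A":
            raise ValueError(f"cannot convert unit {self.unit} to mV")
        return ScalarField(grid=self.grid, values=self.values * E_PER_A_IN_MV,
                           unit="mV", meta=dict(self.meta))


@dataclass
class ElectricalDistanceProfile:
    """δ(z): fraction of the applied voltage dropped below height z."""

    z: np.ndarray
    delta: np.ndarray
    cylinder_radius: float
    intra_range: tuple[float, float]
    extra_range: tuple[float, float]

    def __call__(self, z: float | np.ndarray) -> np.ndarray:
        zq = np.asarray(z, dtype=float)
        if np.any(zq < self.z[0] - 1e-9) or np.any(zq > self.z[-1] + 1e-9):
            raise ValueError("z outside the profile range")
        return np.interp(zq, self.z, self.delta)


def effective_sigma(sigma: float, grid: GridSpec) -> float:
    return max(sigma, float(grid.spacing.min()) / 2.0)


def _cic_deposit(system: ChargeSystem, grid: GridSpec) -> np.ndarray:
    """Cloud-in-cell (trilinear) charge assignment on the periodic grid."""
    rho = np.zeros(grid.dims)
    if len(system.charges) == 0:
        return rho
    dims = np.array(grid.dims)
    frac = (system.positions - grid.origin) / grid.spacing
    i0 = np.floor(frac).astype(int)
    w1 = frac - i0
    w0 = 1.0 - w1
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = ((w1[:, 0] if dx else w0[:, 0])
                     * (w1[:, 1] if dy else w0[:, 1])
                     * (w1[:, 2] if dz else w0[:, 2]))
                idx = (i0 + np.array([dx, dy, dz])) % dims
                np.add.at(rho, (idx[:, 0], idx[:, 1], idx[:, 2]),
                          system.charges * w)
    return rho / grid.voxel_volume  # e/Å³


def _k_vectors(grid: GridSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ks = [2 * np.pi * np.fft.fftfreq(n, d=h)
          for n, h in zip(grid.dims, grid.spacing)]
    return np.meshgrid(*ks, indexing="ij")


def spread_charges(system: ChargeSystem, grid: GridSpec,
                   sigma: float = 0.15) -> ScalarField:
    """Spread point charges into a Gaussian-smoothed grid density (e/Å³).

    The total gridded charge equals Σ qᵢ exactly (the k = 0 mode is untouched
    by the attenuation).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    sig = effective_sigma(sigma, grid)
    rho = _cic_deposit(system, grid)
    kx, ky, kz = _k_vectors(grid)
    k2 = kx**2 + ky**2 + kz**2
    rho_k = np.fft.fftn(rho) * np.exp(-0.5 * k2 * sig**2)
    rho_s = np.fft.ifftn(rho_k).real
    return ScalarField(grid=grid, values=rho_s, unit="e_per_A3",
                       meta={"sigma_requested_A": sigma,
                             "sigma_effective_A": sig,
                             "boundaries": "periodic",
                             "assignment": "cloud-in-cell"})


def solve_poisson(density: ScalarField) -> ScalarField:
    """Spectral solution of ∇²Φ = −4πρ on the periodic grid (mean-zero gauge)."""
    if density.unit != "e_per_A3":
        raise ValueError("density must be in e_per_A3")
    kx, ky, kz = _k_vectors(density.grid)
    k2 = kx**2 + ky**2 + kz**2
    rho_k = np.fft.fftn(density.values)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_k = np.where(k2 > 0, 4 * np.pi * rho_k / k2, 0.0)
    phi = np.fft.ifftn(phi_k).real
    meta = dict(density.meta)
    meta["gauge"] = "mean-zero (uniform neutralizing background)"
    return ScalarField(grid=density.grid, values=phi, unit="e_per_A",
                       meta=meta)


def potential_of(system: ChargeSystem, grid: GridSpec,
                 sigma: float = 0.15) -> ScalarField:
    """Convenience: spread + solve in one step."""
    return solve_poisson(spread_charges(system, grid, sigma))


def average_potential(frames: Sequence[ChargeSystem], grid: GridSpec,
                      sigma: float = 0.15) -> ScalarField:
    """Per-voxel mean of per-frame potentials over charge-system frames."""
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    box0 = frames[0].box
    acc = np.zeros(grid.dims)
    for fr in frames:
        if np.any(np.abs(fr.box - box0) > 0.01 * box0):
            raise ValueError("frame boxes differ by more than 1%; "
                             "a single grid would be invalid")
        acc += potential_of(fr, grid, sigma).values
    out = potential_of(frames[0], grid, sigma)  # carries metadata
    return ScalarField(grid=grid, values=acc / len(frames), unit="e_per_A",
                       meta={**out.meta, "n_frames": len(frames)})


def _cylinder_mask(grid: GridSpec, axis_xy: tuple[float, float] | None,
                   radius: float) -> np.ndarray:
    box = grid.box
    cx, cy = axis_xy if axis_xy is not None else (box[0] / 2, box[1] / 2)
    x = grid.axis_coords(0)
    y = grid.axis_coords(1)
    dx = x - cx
    dx -= np.round(dx / box[0]) * box[0]
    dy = y - cy
    dy -= np.round(dy / box[1]) * box[1]
    return (dx[:, None]**2 + dy[None, :]**2) <= radius**2


def electrical_distance(phi_v: ScalarField, phi_0: ScalarField,
                        axis_xy: tuple[float, float] | None = None,
                        cylinder_radius: float = 5.0,
                        bulk_ranges: tuple[tuple[float, float],
                                           tuple[float, float]] | None = None,
                        ) -> ElectricalDistanceProfile:
    """Voltage-normalized axial profile of the potential difference.

    ``bulk_ranges`` gives the (intracellular, extracellular) z-intervals used
    as anchors; the defaults (8–25% and 75–92% of the box height) stay clear
    of both the membrane slab and the periodic z boundary.  δ is 0 on the
    intracellular anchor and 1 on the extracellular anchor by construction.
    """
    if phi_v.grid.dims != phi_0.grid.dims or np.any(
            np.abs(phi_v.grid.spacing - phi_0.grid.spacing) > 1e-9):
        raise ValueError("potential grids do not match")
    if phi_v.unit != phi_0.unit:
        raise ValueError("potential units do not match")
    grid = phi_v.grid
    z = grid.axis_coords(2)
    box_z = grid.box[2]
    if bulk_ranges is None:
        bulk_ranges = ((z[0] + 0.08 * box_z, z[0] + 0.25 * box_z),
                       (z[0] + 0.75 * box_z, z[0] + 0.92 * box_z))
    (ilo, ihi), (elo, ehi) = bulk_ranges
    if max(ilo, elo) < min(ihi, ehi):
        raise ValueError("bulk ranges must not overlap")
    mask = _cylinder_mask(grid, axis_xy, cylinder_radius)
    if not mask.any():
        raise ValueError("cylinder contains no voxels")
    diff = phi_v.values - phi_0.values
    d_z = diff[mask, :].mean(axis=0)

    intra_sel = (z >= ilo) & (z <= ihi)
    extra_sel = (z >= elo) & (z <= ehi)
    if not intra_sel.any() or not extra_sel.any():
        raise ValueError("bulk ranges select no grid planes")
    d_intra = d_z[intra_sel].mean()
    d_extra = d_z[extra_sel].mean()
    denom = d_extra - d_intra
    scale = max(abs(d_z).max(), 1.0)
    if abs(denom) < 1e-9 * scale:
        raise DegenerateVoltageError(
            "bulk-to-bulk potential difference is (near) zero; "
            "cannot normalize the electrical distance")
    delta = (d_z - d_intra) / denom
    return ElectricalDistanceProfile(
        z=z, delta=delta, cylinder_radius=cylinder_radius,
        intra_range=(float(ilo), float(ihi)),
        extra_range=(float(elo), float(ehi)))


def gating_charge(profile: ElectricalDistanceProfile,
                  state1: Sequence[tuple[float, float]],
                  state2: Sequence[tuple[float, float]]) -> float:
    """Q = Σᵢ qᵢ [δ(zᵢ^λ2) − δ(zᵢ^λ1)] in elementary charge units.

    ``state1`` and ``state2`` list (charge e, z Å) for the same charges in
    the two conformational/occupancy states; δ is linearly interpolated on
    the profile's z-grid.
    """
    if len(state1) != len(state2):
        raise ValueError("states must list the same charges")
    q = 0.0
    for (q1, z1), (q2, z2) in zip(state1, state2):
        if abs(q1 - q2) > 1e-12:
            raise ValueError("charges must match between states")
        q += q1 * (float(profile(z2)) - float(profile(z1)))
    return q


def write_dx(fieldobj: ScalarField, path) -> None:
    """Write a ScalarField in OpenDX grid format."""
    g = fieldobj.grid
    nx, ny, nz = g.dims
    with open(path, "w") as fh:
        fh.write(f"# kcvtools scalar field, unit={fieldobj.unit}\n")
        for key, val in fieldobj.meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*g.origin))
        fh.write(f"delta {g.spacing[0]:.6f} 0 0\n")
        fh.write(f"delta 0 {g.spacing[1]:.6f} 0\n")
        fh.write(f"delta 0 0 {g.spacing[2]:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items "
                 f"{nx * ny * nz} data follows\n")
        flat = fieldobj.values.ravel(order="C")
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "field" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')
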