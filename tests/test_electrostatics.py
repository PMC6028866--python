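"""Charge spreading, Poisson solver, δ(z) profile, and gating charge."""

import numpy as np
import pytest
from scipy.special import erf

from kcvtools import electrostatics as es
from kcvtools.electrostatics import (ChargeSystem, DegenerateVoltageError,
                                     GridSpec, average_potential,
                                     electrical_distance, gating_charge,
                                     potential_of, solve_poisson,
                                     spread_charges)


def _grid(box=(24.0, 24.0, 24.0), spacing=1.5):
    return GridSpec.from_box(np.array(box), spacing=spacing)


class TestSpreadCharges:
    def test_charge_conservation(self):
        grid = _grid()
        sys = ChargeSystem(positions=[[5.2, 7.9, 11.3]], charges=[1.0],
                           box=grid.box)
        rho = spread_charges(sys, grid, sigma=0.15)
        assert rho.integral() == pytest.approx(1.0, abs=1e-9)

    def test_zero_charges_zero_field(self):
        grid = _grid()
        sys = ChargeSystem(positions=np.zeros((0, 3)), charges=[],
                           box=grid.box)
        rho = spread_charges(sys, grid)
        assert np.all(rho.values == 0.0)

    def test_superposition(self):
        grid = _grid()
        a = ChargeSystem(positions=[[5.0, 5.0, 5.0]], charges=[1.0],
                         box=grid.box)
        b = ChargeSystem(positions=[[12.0, 9.0, 17.0]], charges=[1.0],
                         box=grid.box)
        ab = ChargeSystem(positions=np.vstack([a.positions, b.positions]),
                          charges=[1.0, 1.0], box=grid.box)
        lhs = spread_charges(ab, grid).values
        rhs = spread_charges(a, grid).values + spread_charges(b, grid).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_effective_width_clamped_to_grid(self):
        grid = _grid()
        sys = ChargeSystem(positions=[[5.0, 5.0, 5.0]], charges=[1.0],
                          box=grid.box)
        rho = spread_charges(sys, grid, sigma=0.15)
        assert rho.meta["sigma_effective_A"] == pytest.approx(
            grid.spacing.min() / 2)


class TestPoisson:
    def test_zero_density_zero_potential(self):
        grid = _grid()
        rho = es.ScalarField(grid=grid, values=np.zeros(grid.dims),
                             unit="e_per_A3")
        phi = solve_poisson(rho)
        assert np.all(phi.values == 0.0)

    def test_single_gaussian_matches_closed_form(self):
        """Spectral solve vs the analytic erf potential of a Gaussian charge.

        The periodic solution equals the isolated closed form plus a constant
        and a small quadratic background term inside r << L.
        """
        L = 64.0
        grid = GridSpec.from_box([L, L, L], spacing=1.5)
        sys = ChargeSystem(positions=[[L / 2, L / 2, L / 2]], charges=[1.0],
                           box=grid.box)
        sigma = 1.0
        phi = potential_of(sys, grid, sigma=sigma)
        sig = es.effective_sigma(sigma, grid)
        X, Y, Z = np.meshgrid(*[grid.axis_coords(a) for a in range(3)],
                              indexing="ij")
        r = np.sqrt((X - L / 2) ** 2 + (Y - L / 2) ** 2 + (Z - L / 2) ** 2)
        mask = (r > 3 * sig) & (r < L / 6)
        closed = erf(r[mask] / (sig * np.sqrt(2))) / r[mask] \
            + 2 * np.pi * r[mask] ** 2 / (3 * L ** 3)
        resid = phi.values[mask] - closed
        offset = resid.mean()  # periodic background constant
        rel = np.abs(resid - offset) / np.abs(closed)
        assert rel.max() < 0.01

    def test_matches_direct_spectral_sum_oracle(self):
        """Grid-assignment route vs an exact-structure-factor Ewald sum."""
        box = np.array([24.0, 24.0, 24.0])
        grid = GridSpec.from_box(box, spacing=1.5)
        pos = np.array([11.2, 12.7, 9.4])
        sys = ChargeSystem(positions=[pos], charges=[1.0], box=box)
        sigma = 1.2
        phi = potential_of(sys, grid, sigma=sigma)
        kx, ky, kz = es._k_vectors(grid)
        k2 = kx**2 + ky**2 + kz**2
        probe_idx = [(4, 4, 4), (10, 3, 8), (2, 12, 6)]
        V = np.prod(box)
        for idx in probe_idx:
            rvec = np.array([grid.axis_coords(a)[idx[a]] for a in range(3)])
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(
                    k2 > 0,
                    4 * np.pi / (V * k2) * np.exp(-0.5 * k2 * sigma**2)
                    * np.cos(kx * (rvec[0] - pos[0])
                             + ky * (rvec[1] - pos[1])
                             + kz * (rvec[2] - pos[2])), 0.0)
            oracle = terms.sum()
            assert phi.values[idx] == pytest.approx(
                oracle, rel=0.02, abs=5e-4)

    def test_linearity(self):
        grid = _grid()
        a = ChargeSystem(positions=[[5.0, 6.0, 7.0]], charges=[1.0],
                         box=grid.box)
        b = ChargeSystem(positions=[[15.0, 16.0, 10.0]], charges=[-2.0],
                         box=grid.box)
        ab = ChargeSystem(positions=np.vstack([a.positions, b.positions]),
                          charges=[1.0, -2.0], box=grid.box)
        lhs = potential_of(ab, grid).values
        rhs = potential_of(a, grid).values + potential_of(b, grid).values
        scale = np.abs(lhs).max()
        np.testing.assert_allclose(lhs, rhs, atol=1e-10 * scale)

    def test_translation_equivariance_by_one_voxel(self):
        grid = _grid()
        pos = np.array([[5.0, 6.0, 7.0]])
        sys = ChargeSystem(positions=pos, charges=[1.0], box=grid.box)
        shift = np.array([grid.spacing[0], 0.0, 0.0])
        sys2 = ChargeSystem(positions=pos + shift, charges=[1.0],
                            box=grid.box)
        phi1 = potential_of(sys, grid).values
        phi2 = potential_of(sys2, grid).values
        np.testing.assert_allclose(phi2, np.roll(phi1, 1, axis=0),
                                   atol=1e-12)

    def test_mean_zero_gauge(self):
        grid = _grid()
        sys = ChargeSystem(positions=[[5.0, 5.0, 5.0]], charges=[1.0],
                          box=grid.box)
        phi = potential_of(sys, grid)
        assert abs(phi.values.mean()) < 1e-12


class TestAveragePotential:
    def test_identical_frames_equal_single(self):
        grid = _grid()
        sys = ChargeSystem(positions=[[5.0, 5.0, 5.0]], charges=[1.0],
                          box=grid.box)
        avg = average_potential([sys, sys, sys], grid)
        np.testing.assert_allclose(avg.values, potential_of(sys, grid).values,
                                   atol=1e-14)

    def test_opposite_charges_cancel(self):
        grid = _grid()
        a = ChargeSystem(positions=[[5.0, 5.0, 5.0]], charges=[1.0],
                         box=grid.box)
        b = ChargeSystem(positions=[[5.0, 5.0, 5.0]], charges=[-1.0],
                         box=grid.box)
        avg = average_potential([a, b], grid)
        np.testing.assert_allclose(avg.values, 0.0, atol=1e-14)

    def test_jittered_frames_smooth_mean(self):
        rng = np.random.default_rng(0)
        grid = _grid()
        base = np.array([12.0, 12.0, 12.0])
        frames = [ChargeSystem(positions=[base + rng.normal(0, 0.1, 3)],
                               charges=[1.0], box=grid.box)
                  for _ in range(250)]
        avg = average_potential(frames, grid, sigma=1.0)
        ref = potential_of(ChargeSystem(positions=[base], charges=[1.0],
                                        box=grid.box), grid, sigma=1.0)
        X, Y, Z = np.meshgrid(*[grid.axis_coords(a) for a in range(3)],
                              indexing="ij")
        r = np.sqrt(((np.stack([X, Y, Z], -1) - base) ** 2).sum(-1))
        # beyond ~2 grid spacings, where sub-voxel assignment error is small
        mask = (r > 3.0) & (r < 8.0)
        rel = np.abs(avg.values[mask] - ref.values[mask]) \
            / np.abs(ref.values[mask]).max()
        assert rel.max() < 0.01

    def test_inconsistent_boxes_rejected(self):
        grid = _grid()
        a = ChargeSystem(positions=[[5.0, 5.0, 5.0]], charges=[1.0],
                         box=grid.box)
        b = ChargeSystem(positions=[[5.0, 5.0, 5.0]], charges=[1.0],
                         box=grid.box * 1.2)
        with pytest.raises(ValueError, match="box"):
            average_potential([a, b], grid)


class TestElectricalDistance:
    def test_identical_potentials_degenerate(self, capacitor_profile):
        phi = capacitor_profile["phi_0"]
        with pytest.raises(DegenerateVoltageError):
            electrical_distance(phi, phi)

    def test_capacitor_delta_rises_zero_to_one(self, capacitor_profile):
        prof = capacitor_profile["profile"]
        z, d = prof.z, prof.delta
        intra = (z >= prof.intra_range[0]) & (z <= prof.intra_range[1])
        extra = (z >= prof.extra_range[0]) & (z <= prof.extra_range[1])
        assert abs(d[intra].mean()) < 1e-9
        assert d[extra].mean() == pytest.approx(1.0, abs=0.01)

    def test_capacitor_delta_matches_closed_form_inside_slab(
            self, capacitor_profile):
        prof = capacitor_profile["profile"]
        z1, z2 = capacitor_profile["slab"]
        inside = (prof.z > z1) & (prof.z < z2)
        lin = (prof.z[inside] - z1) / (z2 - z1)
        assert np.abs(prof.delta[inside] - lin).max() < 0.02

    def test_measured_drop_matches_target(self, capacitor_profile):
        phi_v = capacitor_profile["phi_v"].to_millivolts()
        phi_0 = capacitor_profile["phi_0"].to_millivolts()
        prof = capacitor_profile["profile"]
        grid = capacitor_profile["grid"]
        mask = es._cylinder_mask(grid, None, 5.0)
        dz = (phi_v.values - phi_0.values)[mask, :].mean(axis=0)
        z = grid.axis_coords(2)
        intra = (z >= prof.intra_range[0]) & (z <= prof.intra_range[1])
        extra = (z >= prof.extra_range[0]) & (z <= prof.extra_range[1])
        drop = dz[extra].mean() - dz[intra].mean()
        assert drop == pytest.approx(500.0, rel=0.01)

    def test_gauge_invariance(self, capacitor_profile):
        phi_v = capacitor_profile["phi_v"]
        phi_0 = capacitor_profile["phi_0"]
        shifted = es.ScalarField(grid=phi_v.grid, values=phi_v.values + 3.7,
                                 unit=phi_v.unit)
        a = electrical_distance(phi_v, phi_0).delta
        b = electrical_distance(shifted, phi_0).delta
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestGatingCharge:
    def test_no_motion_zero_charge(self, capacitor_profile):
        prof = capacitor_profile["profile"]
        assert gating_charge(prof, [(1.0, 30.0)], [(1.0, 30.0)]) == 0.0

    def test_defining_equation_direct(self):
        prof = es.ElectricalDistanceProfile(
            z=np.array([0.0, 10.0, 20.0, 30.0]),
            delta=np.array([0.0, 0.10, 0.35, 1.0]),
            cylinder_radius=5.0, intra_range=(0, 2), extra_range=(28, 30))
        q = gating_charge(prof, [(1.0, 10.0)], [(1.0, 20.0)])
        assert q == pytest.approx(0.25, abs=1e-12)

    def test_full_traversal_carries_unit_charge(self, capacitor_profile):
        prof = capacitor_profile["profile"]
        z_intra = np.mean(prof.intra_range)
        z_extra = np.mean(prof.extra_range)
        q = gating_charge(prof, [(1.0, z_intra)], [(1.0, z_extra)])
        assert q == pytest.approx(1.0, abs=0.01)

    def test_telescoping_additivity(self, capacitor_profile):
        prof = capacitor_profile["profile"]
        a, b, c = 10.0, 28.0, 50.0
        q_ab = gating_charge(prof, [(1.0, a)], [(1.0, b)])
        q_bc = gating_charge(prof, [(1.0, b)], [(1.0, c)])
        q_ac = gating_charge(prof, [(1.0, a)], [(1.0, c)])
        assert q_ab + q_bc == pytest.approx(q_ac, abs=1e-12)

    def test_partition_steps_sum_to_unity(self, capacitor_profile):
        """Per-site Q steps across any partition of the membrane sum to 1 e."""
        prof = capacitor_profile["profile"]
        z_intra = np.mean(prof.intra_range)
        z_extra = np.mean(prof.extra_range)
        stops = np.linspace(z_intra, z_extra, 6)  # 5 hops, like S5..S0
        steps = [gating_charge(prof, [(1.0, a)], [(1.0, b)])
                 for a, b in zip(stops, stops[1:])]
        assert sum(steps) == pytest.approx(1.0, abs=0.01)

    def test_out_of_range_z_rejected(self, capacitor_profile):
        prof = capacitor_profile["profile"]
        with pytest.raises(ValueError):
            gating_charge(prof, [(1.0, -100.0)], [(1.0, 0.0)])


def test_dx_writer_roundtrip_values(tmp_path, capacitor_profile):
    from kcvtools.electrostatics import write_dx

    phi = capacitor_profile["phi_v"].to_millivolts()
    path = tmp_path / "phi.dx"
    write_dx(phi, path)
    text = path.read_text().splitlines()
    counts = next(l for l in text if l.startswith("object 1"))
    assert counts.split()[-3:] == [str(d) for d in phi.grid.dims]
    data = []
    in_data = False
    for line in text:
        if line.startswith("object 3"):
            in_data = True
            continue
        if in_data:
            if line.startswith("attribute"):
                break
            data.extend(float(v) for v in line.split())
    np.testing.assert_allclose(np.array(data),
                               phi.values.ravel(order="C"), rtol=1e-5)
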