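import numpy as np
import pytest

from kcvtools import synthetic, transport
from kcvtools.model import OrientedFrameSet


@pytest.fixture(scope="session")
def scaffold():
    return synthetic.make_filter_scaffold()


@pytest.fixture(scope="session")
def cycle_run(scaffold):
    """Scripted conduction-cycle trajectory (jitter-free) plus expectations."""
    schedule, n_frames, expected = synthetic.conduction_cycle_schedule(seed=7)
    topo, traj = synthetic.script_trajectory(scaffold, schedule, n_frames)
    oriented = OrientedFrameSet(trajectory=traj, reference_frame=0,
                                align_selection=topo.select_names(["CA"]))
    return dict(schedule=schedule, n_frames=n_frames, expected=expected,
                topo=topo, traj=traj, oriented=oriented)


@pytest.fixture(scope="session")
def sites(scaffold):
    return transport.BindingSiteSet.from_scaffold(scaffold)


def oriented_from(topo, traj):
    return OrientedFrameSet(trajectory=traj, reference_frame=0,
                            align_selection=topo.select_names(["CA"]))


@pytest.fixture(scope="session")
def capacitor_profile():
    """Solved δ(z) on the plate-capacitor fixture, shared across tests."""
    from kcvtools import electrostatics as es

    box = np.array([24.0, 24.0, 60.0])
    slab = (24.0, 36.0)
    ref, charged = synthetic.make_plate_capacitor(box, slab, 500.0)
    grid = es.GridSpec.from_box(box, spacing=1.5)
    phi_v = es.potential_of(charged, grid, sigma=0.15)
    phi_0 = es.potential_of(ref, grid, sigma=0.15)
    profile = es.electrical_distance(phi_v, phi_0, cylinder_radius=5.0)
    return dict(box=box, slab=slab, grid=grid, phi_v=phi_v, phi_0=phi_0,
                profile=profile)
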