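#!/usr/bin/env python
"""Build every synthetic input used by the downstream analyses.

Generates the four-fold carbonyl-cage filter scaffold, a scripted
conduction-cycle trajectory, a long two-traversal trajectory on a 344 ns
time base, the voltage-imposing plate-capacitor pair, and the toy bilayer
with one planted binder lipid.  Structures go to results/synthetic/ as PDB,
the planted ground truth as JSON.
"""

import json
from pathlib import Path

import numpy as np

from kcvtools import io, synthetic

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scaffold = synthetic.make_filter_scaffold()
    io.write_structure(scaffold.topology, scaffold.trajectory,
                       OUT / "filter_scaffold.pdb")
    print(f"scaffold: {scaffold.topology.n_atoms} atoms, "
          f"{sum(len(p) for p in scaffold.plane_oxygen_ids)} cage oxygens, "
          f"planes at {np.round(scaffold.spec.site_plane_z, 2).tolist()} Å")

    schedule, n_frames, expected = synthetic.conduction_cycle_schedule(
        seed=SEED, jitter_sd=0.1)
    topo, traj = synthetic.script_trajectory(scaffold, schedule, n_frames)
    io.write_structure(topo, traj, OUT / "conduction_cycle.pdb")
    print(f"conduction cycle: {n_frames} frames, "
          f"{len(schedule.particles)} tracked particles")

    trav, n_planted = synthetic.traversal_schedule(2, 200, seed=SEED + 1,
                                                   jitter_sd=0.1)
    ttopo, ttraj = synthetic.script_trajectory(scaffold, trav, 200,
                                               dt_ps=344_000.0 / 199)
    io.write_structure(ttopo, ttraj, OUT / "traversals.pdb")
    print(f"traversal run: {n_planted} planted outward events over "
          f"{ttraj.duration_ns:.0f} ns")

    bilayer = synthetic.make_toy_bilayer(seed=SEED, n_frames=100)
    io.write_structure(bilayer.topology, bilayer.trajectory,
                       OUT / "toy_bilayer.pdb")
    print(f"toy bilayer: binder lipid planted at residue "
          f"{bilayer.target_residue}, bound fraction "
          f"{bilayer.bound_fraction:.2f}")

    with open(OUT / "ground_truth.json", "w") as fh:
        json.dump({
            "seed": SEED,
            "expected_configurations": expected,
            "planted_outward_events": n_planted,
            "binder_residue": bilayer.target_residue,
            "binder_bound_fraction": bilayer.bound_fraction,
        }, fh, indent=1)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
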