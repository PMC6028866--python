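#!/usr/bin/env python
"""Electrical-distance profile δ(z) and per-step gating charges.

Solves the periodic Poisson equation on a 1.5 Å grid for the synthetic
voltage-imposing plate system and its zero-charge reference, normalizes the
cylinder-averaged potential difference into δ(z), and integrates gating
charges for single-ion hops across an even partition of the membrane slab —
the per-step charges must telescope to 1 e for a full traversal.
"""

from pathlib import Path

import numpy as np

from kcvtools import electrostatics as es
from kcvtools import synthetic

OUT = Path(__file__).resolve().parents[1] / "results" / "epot"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    box = np.array([24.0, 24.0, 60.0])
    slab = (0.4 * box[2], 0.6 * box[2])
    ref, charged = synthetic.make_plate_capacitor(box, slab,
                                                  target_drop_mV=500.0)
    grid = es.GridSpec.from_box(box, spacing=1.5)
    phi_v = es.potential_of(charged, grid, sigma=0.15)
    phi_0 = es.potential_of(ref, grid, sigma=0.15)
    es.write_dx(phi_v.to_millivolts(), OUT / "potential_mV.dx")

    profile = es.electrical_distance(phi_v, phi_0, cylinder_radius=5.0)
    np.savetxt(OUT / "electrical_distance.csv",
               np.column_stack([profile.z, profile.delta]), delimiter=",",
               header="z_A,delta", comments="")
    z, d = profile.z, profile.delta
    intra = (z >= profile.intra_range[0]) & (z <= profile.intra_range[1])
    extra = (z >= profile.extra_range[0]) & (z <= profile.extra_range[1])
    print(f"delta at intracellular bulk: {d[intra].mean():+.4f}")
    print(f"delta at extracellular bulk: {d[extra].mean():+.4f}")

    # five hops from bulk to bulk, mimicking S5->S4->...->S0->solution steps
    stops = np.linspace(np.mean(profile.intra_range),
                        np.mean(profile.extra_range), 6)
    steps = [es.gating_charge(profile, [(1.0, a)], [(1.0, b)])
             for a, b in zip(stops, stops[1:])]
    print("per-hop gating charge (e):",
          " + ".join(f"{q:.3f}" for q in steps),
          f"= {sum(steps):.3f}")
    q_full = es.gating_charge(
        profile, [(1.0, np.mean(profile.intra_range))],
        [(1.0, np.mean(profile.extra_range))])
    print(f"full intra->extra traversal: Q = {q_full:.3f} e")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
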