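"""Configuration validation and the stage runner.

A run is described by a YAML/JSON config; :func:`validate_config` fills
documented defaults, rejects unknown keys and out-of-range values, and
reports every default it applied.  :func:`run_stages` executes the selected
stages in dependency order over the synthetic systems (or user-supplied
inputs), writing every output table next to a JSON provenance block so an
identical config reproduces all numbers bitwise.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

STAGES = ("synthesize", "core", "transport", "gating", "epot", "lipids",
          "affinity")

#: documented defaults; every leaf is (default, low, high) for numeric keys
_SCHEMA: dict[str, dict] = {
    "transport": {"radial_cutoff": (3.0, 0.0, 20.0),
                  "cavity_radius": (5.0, 0.0, 50.0)},
    "gating": {"eps": (0.5, 1e-9, 100.0), "min_samples": (10, 1, 10_000),
               "window_ns": (1.0, 0.0, 1e6)},
    "epot": {"spacing": (1.5, 0.1, 20.0), "sigma": (0.15, 1e-6, 50.0),
             "cylinder_radius": (5.0, 0.1, 100.0),
             "target_drop_mV": (500.0, -1e6, 1e6)},
    "lipids": {"cutoff": (1.0, 0.0, 50.0), "voxel": (1.0, 0.1, 20.0),
               "atom_radius": (1.0, 0.0, 20.0),
               "threshold": (0.15, 0.0, 1.0)},
    "core": {"contact_samples": (370, 1, 1_000_000),
             "truncation_nm": (1.5, 0.01, 100.0)},
    "synthesize": {"n_frames": (80, 10, 1_000_000),
                   "jitter_sd": (0.1, 0.0, 5.0),
                   "bilayer_frames": (100, 10, 1_000_000)},
}


class ConfigError(ValueError):
    pass


class DependencyError(RuntimeError):
    pass


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    stages: list[str]
    params: dict[str, dict]
    inputs: dict[str, Path] = dc_field(default_factory=dict)
    defaults_applied: list[str] = dc_field(default_factory=list)


def validate_config(path) -> RunConfig:
    """Load and validate a run config, filling documented defaults.

    Unknown keys are errors (no silent typos); numeric parameters are range
    checked; referenced input paths must exist; a seed is mandatory because
    the synthetic stages are stochastic.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known_top = {"seed", "outdir", "stages", "inputs"} | set(_SCHEMA)
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if "seed" not in raw:
        raise ConfigError("config must set an explicit integer seed")
    seed = int(raw["seed"])
    outdir = Path(raw.get("outdir", "results/run"))
    stages = list(raw.get("stages", STAGES))
    bad = set(stages) - set(STAGES)
    if bad:
        raise ConfigError(f"unknown stage(s): {sorted(bad)}")

    params: dict[str, dict] = {}
    defaults_applied: list[str] = []
    for section, schema in _SCHEMA.items():
        given = raw.get(section, {}) or {}
        unknown = set(given) - set(schema)
        if unknown:
            raise ConfigError(
                f"unknown key(s) in section {section!r}: {sorted(unknown)}")
        params[section] = {}
        for key, (default, lo, hi) in schema.items():
            if key in given:
                val = given[key]
                if not (lo <= val <= hi):
                    raise ConfigError(
                        f"{section}.{key}={val} outside [{lo}, {hi}]")
            else:
                val = default
                defaults_applied.append(f"{section}.{key}={default}")
            params[section][key] = val

    inputs = {}
    for key, p in (raw.get("inputs") or {}).items():
        if key not in ("structure", "trajectory", "charge_table"):
            raise ConfigError(f"unknown input key {key!r}")
        p = Path(p)
        if not p.exists():
            raise DependencyError(f"input {key} does not exist: {p}")
        inputs[key] = p
    return RunConfig(seed=seed, outdir=outdir, stages=stages, params=params,
                     inputs=inputs, defaults_applied=defaults_applied)


def _provenance(outdir: Path, stage: str, params: dict, seed: int,
                outputs: list[str]) -> None:
    import kcvtools

    block = {"stage": stage, "parameters": params, "seed": seed,
             "outputs": outputs, "kcvtools_version": kcvtools.__version__}
    with open(outdir / f"{stage}.provenance.json", "w") as fh:
        json.dump(block, fh, indent=1, sort_keys=True)


def run_stages(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns a run report (per-stage wall time, headline numbers, output
    files).  Raises :class:`DependencyError` when a stage needs an upstream
    product that was neither scheduled nor supplied.
    """
    from . import affinity, gating, geometry, lipids, synthetic, transport
    from .electrostatics import (GridSpec, electrical_distance, potential_of,
                                 write_dx)
    from .geometry import orient_frames
    from .model import OrientedFrameSet

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "outputs": []}
    state: dict = {}
    ordered = [s for s in STAGES if s in config.stages]

    needs_synth = {"core", "transport", "gating", "lipids"}
    for stage in ordered:
        t0 = time.perf_counter()
        params = config.params.get(stage, {})
        outputs: list[str] = []

        if stage in needs_synth and "scaffold" not in state \
                and "synthesize" not in ordered and not config.inputs:
            raise DependencyError(
                f"stage {stage!r} needs synthesized or supplied inputs")

        if stage == "synthesize":
            p = config.params["synthesize"]
            scaffold = synthetic.make_filter_scaffold()
            cyc_schedule, n_cyc, expected = synthetic.conduction_cycle_schedule(
                seed=config.seed, jitter_sd=p["jitter_sd"])
            topo, traj = synthetic.script_trajectory(
                scaffold, cyc_schedule, n_cyc,
                flips=[(n_cyc // 2, 64, "A", "helix_facing"),
                       (3 * n_cyc // 4, 64, "A", "pore_facing")])
            trav_schedule, n_planted = synthetic.traversal_schedule(
                2, p["n_frames"], seed=config.seed + 1,
                jitter_sd=p["jitter_sd"])
            # time base scaled so two traversals correspond to a long run
            ttopo, ttraj = synthetic.script_trajectory(
                scaffold, trav_schedule, p["n_frames"],
                dt_ps=344_000.0 / (p["n_frames"] - 1))
            bilayer = synthetic.make_toy_bilayer(seed=config.seed,
                                                 n_frames=p["bilayer_frames"])
            state.update(scaffold=scaffold, topo=topo, traj=traj,
                         expected_configs=expected, ttopo=ttopo, ttraj=ttraj,
                         n_planted=n_planted, bilayer=bilayer)
            synthetic.ground_truth_json(
                {"expected_configurations": expected,
                 "planted_traversals": n_planted,
                 "seed": config.seed}, out / "ground_truth.json")
            outputs.append("ground_truth.json")

        elif stage == "core":
            scaffold, topo, traj = (state["scaffold"], state["topo"],
                                    state["traj"])
            sel = topo.select_names(["CA"])
            oriented = orient_frames(traj, topo, sel)
            state["oriented"] = oriented
            rmsd = geometry.rmsd_series(oriented, sel)
            np.savetxt(out / "rmsd.csv",
                       np.column_stack([oriented.trajectory.times, rmsd]),
                       delimiter=",", header="time_ps,rmsd_A", comments="")
            cmap = geometry.contact_map(topo=topo, oriented=oriented,
                                        n_samples=config.params["core"]
                                        ["contact_samples"],
                                        truncation=config.params["core"]
                                        ["truncation_nm"])
            cmap.to_dataframe().to_csv(out / "contact_map.csv")
            report["stages"]["core"] = {"rmsd_max_A": float(rmsd.max())}
            outputs += ["rmsd.csv", "contact_map.csv"]

        elif stage == "transport":
            scaffold, topo, traj = (state["scaffold"], state["topo"],
                                    state["traj"])
            oriented = state.get("oriented") or OrientedFrameSet(
                trajectory=traj, reference_frame=0,
                align_selection=topo.select_names(["CA"]))
            sites = transport.BindingSiteSet.from_scaffold(
                scaffold, radial_cutoff=params["radial_cutoff"],
                cavity_radius=params["cavity_radius"])
            ions = topo.atom_ids("ion")
            waters = topo.atom_ids("water")
            ion_series = transport.assign_sites(oriented, topo, sites, ions)
            wat_series = transport.assign_sites(oriented, topo, sites, waters)
            state["ion_series"] = ion_series
            occ = transport.occupancy_table(ion_series)
            occ.to_csv(out / "occupancy.csv", index=False)
            configs = transport.configuration_series(ion_series, wat_series)
            (out / "configurations.txt").write_text("\n".join(configs) + "\n")

            t_oriented = OrientedFrameSet(
                trajectory=state["ttraj"], reference_frame=0,
                align_selection=state["ttopo"].select_names(["CA"]))
            t_series = transport.assign_sites(
                t_oriented, state["ttopo"], sites,
                state["ttopo"].atom_ids("ion"))
            events = transport.count_permeations(t_series, sites)
            transport.events_to_dataframe(events).to_csv(
                out / "permeation_events.csv", index=False)
            current = transport.inferred_current(
                len(events), state["ttraj"].duration_ns)
            report["stages"]["transport"] = {
                "n_events": len(events), "current_pA": current,
                "occupancy": dict(zip(occ["site"], occ["occupancy"]))}
            outputs += ["occupancy.csv", "configurations.txt",
                        "permeation_events.csv"]

        elif stage == "gating":
            scaffold, topo = state["scaffold"], state["topo"]
            oriented = state.get("oriented") or OrientedFrameSet(
                trajectory=state["traj"], reference_frame=0,
                align_selection=topo.select_names(["CA"]))
            desc = gating.descriptors(oriented, topo,
                                      scaffold.residue_indices,
                                      scaffold.subunits)
            refs = synthetic_reference_points(scaffold)
            orient_df = gating.orientation_series(
                desc, refs, eps=params["eps"],
                min_samples=min(params["min_samples"],
                                max(2, oriented.n_frames // 4)))
            orient_df.to_csv(out / "orientation.csv", index=False)
            if "ion_series" in state:
                table = gating.coincidence(orient_df, state["ion_series"],
                                           window_ns=params["window_ns"])
                table.to_csv(out / "coincidence.csv", index=False)
                frac = (float(table["within_window"].mean())
                        if len(table) else float("nan"))
                report["stages"]["gating"] = {
                    "n_flips": int(len(table)), "fraction_within": frac}
                outputs.append("coincidence.csv")
            outputs.append("orientation.csv")

        elif stage == "epot":
            p = params
            box = np.array([24.0, 24.0, 60.0])
            slab = (0.4 * box[2], 0.6 * box[2])
            ref, charged = synthetic.make_plate_capacitor(
                box, slab, target_drop_mV=p["target_drop_mV"])
            grid = GridSpec.from_box(box, spacing=p["spacing"])
            phi_v = potential_of(charged, grid, sigma=p["sigma"])
            phi_0 = potential_of(ref, grid, sigma=p["sigma"])
            profile = electrical_distance(
                phi_v, phi_0, cylinder_radius=p["cylinder_radius"])
            np.savetxt(out / "electrical_distance.csv",
                       np.column_stack([profile.z, profile.delta]),
                       delimiter=",", header="z_A,delta", comments="")
            write_dx(phi_v.to_millivolts(), out / "potential_mV.dx")
            report["stages"]["epot"] = {
                "delta_extracellular": float(profile.delta[-2]),
                "delta_intracellular": float(profile.delta[1])}
            outputs += ["electrical_distance.csv", "potential_mV.dx"]

        elif stage == "lipids":
            bilayer = state.get("bilayer")
            if bilayer is None:
                raise DependencyError("lipids stage needs the synthesize stage")
            b_oriented = OrientedFrameSet(
                trajectory=bilayer.trajectory, reference_frame=0,
                align_selection=bilayer.topology.atom_ids("protein"))
            contacts = lipids.residue_contacts(b_oriented, bilayer.topology,
                                               cutoff=params["cutoff"])
            contacts.to_csv(out / "lipid_contacts.csv", index=False)
            omap = lipids.occupancy_map(b_oriented, bilayer.topology,
                                        voxel=params["voxel"],
                                        atom_radius=params["atom_radius"])
            write_dx(omap.to_field(), out / "lipid_occupancy.dx")
            n_above = int((omap.occupancy > params["threshold"]).sum())
            report["stages"]["lipids"] = {
                "voxels_above_threshold": n_above,
                "top_residue": int(contacts.loc[
                    contacts["mean_count"].idxmax(), "residue"])}
            outputs += ["lipid_contacts.csv", "lipid_occupancy.dx"]

        elif stage == "affinity":
            table = affinity.load_table("kcv_blockers")
            r = affinity.affinity_correlation(table, scale="log")
            table.to_csv(out / "blocker_affinities.csv", index=False)
            report["stages"]["affinity"] = {"pearson_r_log": r}
            outputs.append("blocker_affinities.csv")

        _provenance(out, stage, params, config.seed, outputs)
        report["stages"].setdefault(stage, {})
        report["stages"][stage]["wall_s"] = time.perf_counter() - t0
        report["outputs"] += outputs

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def synthetic_reference_points(scaffold):
    """Reference anchors matched to the scaffold's two carbonyl states."""
    from .gating import ReferencePoints, dihedral

    key = (scaffold.residue_indices[0], scaffold.subunits[0])
    topo = scaffold.topology
    ids = {nm: int(np.flatnonzero((topo.residue_indices == key[0])
                                  & (topo.subunit_ids == key[1])
                                  & (topo.names == nm))[0])
           for nm in ("C", "CA", "N")}
    base = scaffold.trajectory.coordinates[0]
    anchors = {}
    for st in ("pore_facing", "helix_facing"):
        o = scaffold.oxygen_positions[key][st]
        dih = dihedral(base[ids["C"]], base[ids["CA"]], base[ids["N"]], o)
        anchors[st] = (float(dih), float(np.hypot(o[0], o[1])))
    return ReferencePoints(pore_facing=anchors["pore_facing"],
                           helix_facing=anchors["helix_facing"])
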