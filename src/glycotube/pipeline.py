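"""End-to-end driver: build -> assemble -> simulate -> analyze.

Every stage is seeded from the configuration, so a rerun with the same
config is bit-identical for the generated structures, trajectory and
analysis tables.  Outputs are CSV files plus a manifest recording the
package version, parameters and seeds.
"""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import adsorption, conformation, hbond
from .assemble import BoxSpec, IonSpec, assemble
from .fcnt import functionalized_tube
from .glycan import build_decamer, build_monosaccharide
from .io import RunConfig, write_coordinates, write_trajectory
from .trajectory import AdsorptionScenario, TorsionSurfaceSpec, generate

log = logging.getLogger("glycotube")


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a report dict (also written as JSON)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": config.__dict__.copy()}
    report["config"]["analyses"] = list(config.analyses)

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as err:  # noqa: BLE001 - abort with stage name
            raise StageError(name, err) from err
        log.info("stage %-12s %.2f s", name, time.perf_counter() - t0)
        return result

    def _build():
        tube = functionalized_tube(
            chirality_n=config.chirality_n, cells=config.cells,
            group_kind=config.group_kind, coverage=config.coverage,
            seed=config.build_seed,
        )
        if config.glycan_kind in ("HA", "Ch"):
            glycan = build_decamer(config.glycan_kind)
        else:
            glycan = build_monosaccharide(config.glycan_kind)
        return tube, glycan

    tube, glycan = stage("build", _build)
    report["n_tube_atoms"] = tube.n_atoms
    report["tube_net_charge"] = tube.net_charge

    def _assemble():
        box = BoxSpec.for_tube(tube, config.box_xy, config.box_xy)
        return assemble(tube, [glycan], config.copies, box,
                        IonSpec(config.ionic_strength), seed=config.assemble_seed)

    system = stage("assemble", _assemble)
    report["n_atoms"] = system.n_atoms
    report["net_charge"] = system.net_charge
    report["ions"] = {"NA": system.metadata["n_na"], "CL": system.metadata["n_cl"]}
    write_coordinates(out / "system.pdb", system.atoms, system.positions, system.box)

    def _simulate():
        scenario = AdsorptionScenario(facing=config.facing)
        torsions = TorsionSurfaceSpec.single() if glycan.linkages else None
        return generate(system, scenario, torsions=torsions,
                        n_frames=config.n_frames, seed=config.trajectory_seed)

    traj, truth = stage("simulate", _simulate)
    write_trajectory(out / "trajectory.pdb", traj)
    report["n_frames"] = traj.n_frames

    def _analyze():
        results = {}
        sel = traj.indices(molclass="glycan")
        if "rdf" in config.analyses:
            prof = adsorption.radial_profile(traj, sel, label="glycan")
            pd.DataFrame(
                dict(r_center=prof.centers, counts=prof.counts)
            ).to_csv(out / "rdf.csv", index=False)
            lm = adsorption.layer_metrics(prof)
            results["rdf"] = dict(
                total_counts=prof.total,
                fraction_within_15=lm.fraction_within_15,
                fraction_within_20=lm.fraction_within_20,
                decay_radius=lm.decay_radius,
            )
        if "orientation" in config.analyses and config.glycan_kind not in ("HA", "Ch"):
            o = adsorption.orientation(traj, config.glycan_kind)
            results["orientation"] = dict(
                preferred=o.preferred, peak_a=o.peak_a, peak_b=o.peak_b
            )
        if "detach" in config.analyses:
            ev = adsorption.detachment_events(traj)
            results["detach"] = dict(
                n_events=ev.n_events, beyond_fraction=ev.beyond_fraction
            )
        if "hbond" in config.analyses:
            roles = hbond.assign_roles(traj, config.group_kind)
            counts = hbond.mean_hbonds(traj, roles)
            counts.per_frame.to_csv(out / "hbonds.csv", index=False)
            results["hbond"] = dict(
                mean_carboxyl_acceptor=counts.mean_carboxyl_acceptor,
                mean_carboxyl_donor=counts.mean_carboxyl_donor,
            )
        if "conformation" in config.analyses:
            c1 = conformation.anomeric_carbons(traj)
            fl = conformation.rmsf(traj, c1, fit=False)
            pd.DataFrame(dict(atom_index=c1, rmsf_A=fl)).to_csv(
                out / "rmsf.csv", index=False
            )
            results["conformation"] = dict(mean_rmsf=float(np.mean(fl)))
        return results

    report["analyses"] = stage("analyze", _analyze)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
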