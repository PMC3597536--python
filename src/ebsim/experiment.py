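"""Config-driven experiments: build a structure, run replicates, write results.

Every run directory contains the structure it used, per-replicate trajectory
summaries, snapshot classifications, and a manifest (config + seeds +
version + wall time) from which the outputs can be regenerated bit-identically.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregation import AggregationParams, build_aggregate
from .config import RunConfig
from .dynamics import run_dynamic_simulation
from .io import write_cells_csv, write_edges_csv
from .patterns import classify, normalize_time, pattern_distribution, snapshot
from .rules import run_static_simulation

__all__ = ["run_experiment", "replicate_seeds"]


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Independent per-replicate seeds spawned from one master seed (<2^31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _trajectory_frame(traj) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "step": traj.steps,
            "tau": normalize_time(traj),
            "ucn": traj.ucn,
            "dcn": traj.dcn,
            "frac_pos": traj.fraction_pos,
        }
    )


def run_experiment(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute the experiment described by ``config``; returns the run directory."""
    t0 = time.time()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    agg_cfg = config.aggregation
    params = AggregationParams(
        n_cells=agg_cfg.n_cells,
        box_side=agg_cfg.box_side,
        step_size=agg_cfg.step_size,
        max_iterations=agg_cfg.max_iterations,
        convergence_displacement=agg_cfg.convergence_displacement,
    )
    structure = build_aggregate(
        agg_cfg.n_cells,
        config.radius.to_params(),
        seed=config.seed,
        params=params,
        contact_slack=agg_cfg.contact_slack,
    )
    write_cells_csv(structure, out / "structure_cells.csv")
    write_edges_csv(structure, out / "structure_edges.csv")

    rule = config.rule.to_params()
    cls_params = config.classifier.to_params()
    seeds = replicate_seeds(config.seed, config.replicates)
    runs = []
    classifications = []
    for rep, seed in enumerate(seeds):
        if config.dynamic:
            traj = run_dynamic_simulation(structure, rule, config.growth.to_params(), seed=seed)
            traj.data.to_csv(out / f"growth_rep{rep:02d}.csv", index=False)
            classifications.append(
                {"replicate": rep, "seed": seed, "class": classify(traj.final, cls_params).value}
            )
        else:
            traj = run_static_simulation(structure, rule, max_steps=config.max_steps, seed=seed)
            runs.append(traj)
            _trajectory_frame(traj).to_csv(out / f"trajectory_rep{rep:02d}.csv", index=False)
            k = int(np.abs(normalize_time(traj) - 0.5).argmin())
            classifications.append(
                {
                    "replicate": rep,
                    "seed": seed,
                    "class": classify(snapshot(traj, k), cls_params).value,
                    "completed": traj.completed,
                }
            )
    pd.DataFrame(classifications).to_csv(out / "classifications.csv", index=False)
    if runs:
        pattern_distribution(runs, params=cls_params).to_csv(out / "pattern_distribution.csv")

    manifest = {
        "config": config.model_dump(),
        "master_seed": config.seed,
        "replicate_seeds": seeds,
        "version": __version__,
        "wall_time_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
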