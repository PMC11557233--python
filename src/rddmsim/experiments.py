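"""Sweep orchestration, seed policy and output writing.

A sweep is the Cartesian product of target types, schedules,
relationships, saturation points and production levels, each condition
run for ``n_replicates`` independent replicates.  Seeds are assigned
deterministically — replicate ``r`` of condition ``c`` runs with
``base_seed + 1000 * c + r`` — so results are independent of execution
order and individually reproducible.  Outputs are a per-locus
trajectory CSV, a run-summary JSON embedding the fully resolved config
and all seeds, a sweep grid TSV and a self-inhibition metrics CSV; all
files are written atomically.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig, config_to_dict
from .methylation_engine import SimulationResult, run_simulation
from .stability_stats import (
    ConditionScore,
    StabilityReport,
    assess_stability,
    score_condition,
    sweep_summary,
)
from .target_search import SearchKinetics

__all__ = [
    "SweepSpec",
    "ConditionResult",
    "run_replicates",
    "iter_conditions",
    "run_sweep",
    "replicate_seed",
    "write_run_outputs",
    "write_sweep_outputs",
    "load_summaries",
]

_CONDITION_SEED_STRIDE = 1000


@dataclass
class SweepSpec:
    """Axes of a parameter sweep."""

    production_levels: Sequence[float] = (100, 200, 300, 400, 500, 600, 700)
    saturation_points: Sequence[float | None] = (0.05, 0.10, 0.15, 0.25, 0.50, None)
    schedules: Sequence[str] = ("bursty",)
    target_types: Sequence[str] = ("RNA",)
    relationships: Sequence[str] = ("linear",)
    n_replicates: int = 7
    base_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "production_levels",
            "saturation_points",
            "schedules",
            "target_types",
            "relationships",
        ):
            if len(getattr(self, name)) == 0:
                raise ConfigError(f"sweep.{name} must be non-empty")
        if self.n_replicates < 1:
            raise ConfigError("sweep.n_replicates must be >= 1")


@dataclass
class ConditionResult:
    """One condition's replicates, reports and score."""

    condition: dict[str, Any]
    seeds: list[int]
    results: list[SimulationResult]
    reports: list[StabilityReport]
    score: ConditionScore


def replicate_seed(base_seed: int, condition_index: int, replicate_index: int) -> int:
    """Deterministic per-replicate seed (recorded in every output)."""
    return base_seed + _CONDITION_SEED_STRIDE * condition_index + replicate_index


def _condition_config(base: SimulationConfig, condition: dict[str, Any]) -> SimulationConfig:
    relationship = condition["relationship"]
    saturation = condition["saturation_point"]
    if relationship in ("linear", "saturated_linear"):
        relationship = "linear" if saturation is None else "saturated_linear"
    elif saturation is not None:
        raise ConfigError(
            f"saturation point set for non-linear relationship {relationship!r}"
        )
    production = dataclasses.replace(
        base.production,
        relationship=relationship,
        saturation_point=saturation if relationship == "saturated_linear" else None,
        production_level=condition["production_level"],
        schedule=condition["schedule"],
    )
    kinetics = SearchKinetics.for_target(
        condition["target_type"],
        p_jump=base.kinetics.p_jump,
        p_exit_scan=base.kinetics.p_exit_scan,
        molecule_length=base.kinetics.molecule_length,
        max_occupancy=base.kinetics.max_occupancy,
    )
    return dataclasses.replace(base, production=production, kinetics=kinetics)


def iter_conditions(spec: SweepSpec):
    """Yield (index, condition dict) over the sweep's Cartesian product.

    Combinations of a nonlinear relationship with an explicit saturation
    point are skipped (saturation only modifies the linear rule).
    """
    idx = 0
    for target, schedule, relationship, saturation, level in itertools.product(
        spec.target_types,
        spec.schedules,
        spec.relationships,
        spec.saturation_points,
        spec.production_levels,
    ):
        if relationship not in ("linear", "saturated_linear") and saturation is not None:
            continue
        yield idx, {
            "target_type": target,
            "schedule": schedule,
            "relationship": relationship,
            "saturation_point": saturation,
            "production_level": level,
        }
        idx += 1


def run_replicates(
    config: SimulationConfig,
    n_replicates: int,
    seeds: Sequence[int],
    condition: dict[str, Any] | None = None,
    alpha: float = 0.01,
    baseline: str = "first_generation",
    log: Callable[[str], None] | None = None,
) -> ConditionResult:
    """Run ``n_replicates`` simulations of one condition and score them.

    Stability compares each replicate's final-generation distribution
    to its first-generation distribution (``baseline="initial"``
    compares to the assigned starting vector instead).
    """
    if len(seeds) != n_replicates:
        raise ValueError("one seed per replicate is required")
    results, reports = [], []
    progress = None
    if log is not None:
        progress = lambda gs: log(
            f"  generation {gs.generation}: pool {gs.pool_size}, "
            f"median CHH {float(np.median(gs.methylation)):.4f}"
        )
    for rep, seed in enumerate(seeds):
        res = run_simulation(config, seed=seed, progress=progress)
        rep_report = assess_stability(
            res.stability_baseline(baseline), res.final_methylation, alpha=alpha
        )
        results.append(res)
        reports.append(rep_report)
        if log is not None:
            log(
                f"replicate {rep + 1}/{n_replicates} seed={seed} "
                f"KS p={rep_report.p_value:.4g} stable={rep_report.stable}"
            )
    score = score_condition(reports, condition)
    return ConditionResult(
        condition=dict(condition or {}),
        seeds=list(seeds),
        results=results,
        reports=reports,
        score=score,
    )


def run_sweep(
    base: SimulationConfig,
    spec: SweepSpec,
    log: Callable[[str], None] | None = None,
) -> list[ConditionResult]:
    """Run every condition of the sweep (deterministic given seeds)."""
    out = []
    for idx, condition in iter_conditions(spec):
        cfg = _condition_config(base, condition)
        seeds = [
            replicate_seed(spec.base_seed, idx, r) for r in range(spec.n_replicates)
        ]
        if log is not None:
            log(f"condition {idx}: {condition}")
        out.append(
            run_replicates(cfg, spec.n_replicates, seeds, condition=condition, log=log)
        )
    return out


# ---------------------------------------------------------------------------
# output writing


def _atomic_write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def trajectory_frame(result: SimulationResult) -> pd.DataFrame:
    """Per-locus trajectory table; generation 0 echoes the initial vector."""
    n = result.initial_methylation.size
    rows = [
        pd.DataFrame(
            {
                "locus_id": np.arange(n),
                "generation": 0,
                "chh": result.initial_methylation,
                "cg": result.initial_cg if result.initial_cg is not None else np.nan,
                "cycle_dwell": 0.0,
                "occupancy_rejections": 0,
            }
        )
    ]
    for g in result.generations:
        rows.append(
            pd.DataFrame(
                {
                    "locus_id": np.arange(n),
                    "generation": g.generation,
                    "chh": g.methylation,
                    "cg": g.cg if g.cg is not None else np.nan,
                    "cycle_dwell": g.locus_dwell,
                    "occupancy_rejections": g.locus_rejections,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def summary_dict(
    result: SimulationResult, baseline: str = "first_generation"
) -> dict[str, Any]:
    """JSON-ready run summary embedding the resolved config and seed."""
    report = assess_stability(
        result.stability_baseline(baseline), result.final_methylation
    )
    return {
        "config": config_to_dict(result.config),
        "seed": result.seed,
        "calibration": {
            "dwell_per_percent": _json_float(result.calibration.dwell_per_percent),
            "reference_dwell": result.calibration.reference_dwell,
            "target_gain_pp": result.calibration.target_gain_pp,
        },
        "stability": {
            "ks_statistic": report.ks_statistic,
            "p_value": report.p_value,
            "stable": report.stable,
        },
        "generations": [
            {
                "generation": g.generation,
                "pool_size": g.pool_size,
                "loci_lost": g.loci_lost,
                "occupancy_rejections": g.occupancy_rejections,
                "dwell_per_percent": _json_float(g.dwell_per_percent),
                "mean_dwell": g.mean_dwell,
                "median_methylation": float(np.median(g.methylation)),
            }
            for g in result.generations
        ],
    }


def _json_float(x: float) -> float | None:
    return None if not np.isfinite(x) else float(x)


def write_run_outputs(
    results: Sequence[SimulationResult], outdir: str | Path, prefix: str = "run"
) -> dict[str, Path]:
    """Write trajectory CSV and summary JSON for a set of replicates."""
    outdir = Path(outdir)
    frames = []
    for rep, res in enumerate(results):
        frame = trajectory_frame(res)
        frame.insert(0, "replicate", rep)
        frames.append(frame)
    traj_path = outdir / f"{prefix}_trajectory.csv"
    _atomic_write(traj_path, pd.concat(frames, ignore_index=True).to_csv(index=False))
    summary = {
        "replicates": [summary_dict(res) for res in results],
        "seeds": [res.seed for res in results],
    }
    summary_path = outdir / f"{prefix}_summary.json"
    _atomic_write(summary_path, json.dumps(summary, indent=2))
    return {"trajectory": traj_path, "summary": summary_path}


def write_sweep_outputs(
    condition_results: Sequence[ConditionResult], outdir: str | Path
) -> dict[str, Path]:
    """Write the sweep grid TSV and per-condition summary JSON."""
    outdir = Path(outdir)
    grid = sweep_summary([c.score for c in condition_results])
    grid_path = outdir / "sweep_grid.tsv"
    _atomic_write(grid_path, grid.to_csv(sep="\t", na_rep=""))
    payload = []
    for c in condition_results:
        payload.append(
            {
                "condition": c.condition,
                "seeds": c.seeds,
                "n_replicates": c.score.n_replicates,
                "n_stable": c.score.n_stable,
                "reports": [
                    {
                        "ks_statistic": r.ks_statistic,
                        "p_value": r.p_value,
                        "stable": r.stable,
                    }
                    for r in c.reports
                ],
                "replicates": [summary_dict(res) for res in c.results],
            }
        )
    json_path = outdir / "sweep_conditions.json"
    _atomic_write(json_path, json.dumps(payload, indent=2))
    return {"grid": grid_path, "conditions": json_path}


def load_summaries(directory: str | Path) -> list[dict[str, Any]]:
    """Load stored sweep-condition summaries for the report command."""
    directory = Path(directory)
    path = directory / "sweep_conditions.json"
    if not path.exists():
        raise FileNotFoundError(f"no sweep_conditions.json under {directory}")
    with open(path) as fh:
        return json.load(fh)
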