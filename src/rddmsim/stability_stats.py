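"""Stability scoring of methylation distributions and diagnostic metrics.

A simulation replicate is "stable" when the two-sample Kolmogorov-
Smirnov test between the initially assigned methylation distribution
and the final-generation pre-replication distribution gives p > 0.01 —
i.e. the final distribution is not significantly different from the
starting one.  Conditions are scored by how many of their (typically
seven) replicates are stable, giving the sweep grids; additional
metrics quantify the model's self-inhibition (pool size, loci lost to
zero production, dwell-per-percent, occupancy rejections) and the
per-locus methylation-change distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps

from .methylation_engine import SimulationResult

__all__ = [
    "StabilityReport",
    "ConditionScore",
    "ks_two_sample",
    "assess_stability",
    "score_condition",
    "sweep_summary",
    "self_inhibition_metrics",
    "methylation_change",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class StabilityReport:
    """KS comparison of one replicate's initial and final distributions."""

    ks_statistic: float
    p_value: float
    alpha: float = DEFAULT_ALPHA

    @property
    def stable(self) -> bool:
        return self.p_value > self.alpha


@dataclass(frozen=True)
class ConditionScore:
    """Replicate-stability count for one simulation condition."""

    condition: dict
    n_replicates: int
    n_stable: int


def ks_two_sample(
    a: np.ndarray, b: np.ndarray, method: str = "asymp"
) -> tuple[float, float]:
    """Two-sample KS statistic and p-value.

    The statistic is the maximum absolute difference between the two
    empirical CDFs.  The default p-value uses the asymptotic Kolmogorov
    distribution ``Q(lambda) = 2 * sum_k (-1)^(k-1) exp(-2 k^2 lambda^2)``
    evaluated at ``lambda = (sqrt(en) + 0.12 + 0.11/sqrt(en)) * D`` with
    effective size ``en = n*m/(n+m)`` — the standard asymptotic
    two-sample formula with the Stephens small-sample correction, as
    used by the statistical environments this stability rule originates
    from.  ``method="exact"`` computes the exact permutation-based
    p-value (small samples).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "exact":
        res = sps.ks_2samp(a, b, method="exact")
        return float(res.statistic), float(res.pvalue)
    if method != "asymp":
        raise ValueError(f"unknown method {method!r}")
    d = float(sps.ks_2samp(a, b, method="asymp").statistic)
    en = math.sqrt(a.size * b.size / (a.size + b.size))
    lam = (en + 0.12 + 0.11 / en) * d
    p = float(np.clip(special.kolmogorov(lam), 0.0, 1.0))
    return d, p


def assess_stability(
    initial: np.ndarray,
    final: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    method: str = "asymp",
) -> StabilityReport:
    """Score one replicate: stable iff KS p-value > ``alpha``."""
    initial = np.asarray(initial, dtype=float)
    final = np.asarray(final, dtype=float)
    if initial.shape != final.shape:
        raise ValueError("initial and final vectors must have equal length")
    stat, p = ks_two_sample(initial, final, method=method)
    return StabilityReport(ks_statistic=stat, p_value=p, alpha=alpha)


def score_condition(
    reports: Sequence[StabilityReport], condition: dict | None = None
) -> ConditionScore:
    """Count stable replicates for one condition."""
    return ConditionScore(
        condition=dict(condition or {}),
        n_replicates=len(reports),
        n_stable=sum(1 for r in reports if r.stable),
    )


def sweep_summary(scores: Iterable[ConditionScore]) -> pd.DataFrame:
    """Pivot condition scores into a sweep grid.

    Rows are (target type, schedule, saturation); columns are production
    levels; cells hold ``n_stable``.  Missing cells are left empty.
    """
    rows = []
    seen = set()
    for s in scores:
        c = s.condition
        key = (
            c.get("target_type", "RNA"),
            c.get("schedule", "bursty"),
            c.get("saturation_point"),
            c.get("production_level"),
        )
        if key in seen:
            raise ValueError(f"duplicate condition key {key}")
        seen.add(key)
        rows.append(
            {
                "target_type": key[0],
                "schedule": key[1],
                "saturation": "none" if key[2] is None else key[2],
                "production_level": key[3],
                "n_stable": s.n_stable,
            }
        )
    frame = pd.DataFrame(rows)
    grid = frame.pivot(
        index=["target_type", "schedule", "saturation"],
        columns="production_level",
        values="n_stable",
    )
    return grid.sort_index()


def self_inhibition_metrics(
    results_by_level: dict[float, Sequence[SimulationResult]],
) -> pd.DataFrame:
    """Per-(production level, replicate) self-inhibition diagnostics.

    For each simulation: the mean post-loading AGO:siRNA pool size
    across generations, the mean number of loci whose production
    rounds to zero, the calibrated dwell-per-percent, and the total
    occupancy-rejection count.  Across increasing production levels the
    pool grows linearly while occupancy rejections and dwell-per-percent
    rise — the self-inhibition signature.
    """
    if len(results_by_level) < 2:
        raise ValueError("need at least two production levels")
    rows = []
    for level in sorted(results_by_level):
        for rep, res in enumerate(results_by_level[level]):
            gens = res.generations
            rows.append(
                {
                    "production_level": level,
                    "replicate": rep,
                    "mean_pool_size": float(np.mean([g.pool_size for g in gens])),
                    "loci_lost": float(np.mean([g.loci_lost for g in gens])),
                    "dwell_per_percent": res.calibration.dwell_per_percent,
                    "occupancy_rejections": int(
                        np.sum([g.occupancy_rejections for g in gens])
                    ),
                }
            )
    return pd.DataFrame(rows)


def methylation_change(
    initial: np.ndarray, final: np.ndarray
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-locus methylation deltas (final - initial) and summary stats."""
    initial = np.asarray(initial, dtype=float)
    final = np.asarray(final, dtype=float)
    if initial.shape != final.shape:
        raise ValueError("initial and final vectors must have equal length")
    deltas = final - initial
    summary = {
        "mean": float(deltas.mean()),
        "variance": float(deltas.var(ddof=1)) if deltas.size > 1 else 0.0,
        "std": float(deltas.std(ddof=1)) if deltas.size > 1 else 0.0,
    }
    return deltas, summary
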