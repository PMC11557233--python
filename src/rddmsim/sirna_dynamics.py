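"""siRNA production, AGO loading and replication halving of the pool.

Each RdDM locus produces siRNAs in proportion to its current methylation
under one of four methylation-to-siRNA relationships (linear, linear with
a saturation point, Hill, sigmoid).  Production is scheduled either as a
single burst immediately after replication ("bursty") or at several
evenly spaced timepoints through the cell cycle ("steady").  AGO is
slightly limiting (0.8 AGO per siRNA by default) and loaded AGO:siRNA
complexes are the searching agents of the model; loading is either
proportional per locus or by pooled competition.  Under the carryover
pool policy the complex pool is randomly reduced by half at each
replication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProductionSpec",
    "sirna_count",
    "sirna_counts",
    "production_raw",
    "production_schedule",
    "produce_sirnas",
    "load_ago",
    "allocate_ago",
    "halve_pool",
    "ProductionConfigError",
]

RELATIONSHIPS = ("linear", "saturated_linear", "hill", "sigmoid")


class ProductionConfigError(ValueError):
    """Raised for inconsistent production specifications."""


@dataclass
class ProductionSpec:
    """Methylation-to-siRNA production rule and schedule.

    Parameters
    ----------
    relationship
        One of ``linear``, ``saturated_linear``, ``hill``, ``sigmoid``.
    production_level
        siRNAs produced per unit methylation fraction (the swept
        "siRNA production level", 50-700).  Applies to the linear and
        saturated-linear rules.
    saturation_point
        Methylation fraction above which production stops increasing
        (saturated_linear only; 0.05/0.10/0.15/0.25/0.50 are the swept
        values).
    schedule
        ``bursty`` (one burst at t = 0 of each cycle) or ``steady``
        (``steady_events`` evenly spaced bursts).
    steady_events
        Number of production events under the steady schedule.
    steady_full_production
        When false (default) each steady event produces 1/steady_events
        of the momentary production, so a cycle's total output matches
        a single burst evaluated along the methylation trajectory; when
        true every event produces the full amount.
    ago_per_sirna
        AGO:siRNA loading ratio (0.8 by default: AGO is slightly
        limiting relative to the siRNAs produced).
    loading
        ``proportional`` (default): each locus receives AGO in
        proportion to its own production, stochastically rounded, so
        AGO limitation scales every locus equally; ``competitive``:
        all siRNAs compete for ``floor(ratio * pool)`` AGO proteins,
        selected uniformly without replacement across the pooled
        siRNAs.
    cg_coupled
        When true, production is proportional to total CHH + CG
        methylation.
    hill_amplitude, hill_exponent, hill_half_max
        Hill rule ``A * x^h / (K^h + x^h)`` on methylation percent
        ``x = 100 m``.
    sigmoid_amplitude, sigmoid_half_max
        Hyperbolic rule ``A * x / (K + x)`` on methylation percent.
    """

    relationship: str = "linear"
    production_level: float = 300.0
    saturation_point: float | None = None
    schedule: str = "bursty"
    steady_events: int = 6
    steady_full_production: bool = False
    ago_per_sirna: float = 0.8
    loading: str = "proportional"
    cg_coupled: bool = False
    hill_amplitude: float = 10.0
    hill_exponent: float = 5.0
    hill_half_max: float = 5.0
    sigmoid_amplitude: float = 11.1
    sigmoid_half_max: float = 6.0

    def __post_init__(self) -> None:
        if self.relationship not in RELATIONSHIPS:
            raise ProductionConfigError(f"unknown relationship {self.relationship!r}")
        if self.production_level < 0:
            raise ProductionConfigError("production_level must be >= 0")
        if self.relationship == "saturated_linear":
            if self.saturation_point is None or not 0 < self.saturation_point <= 1:
                raise ProductionConfigError(
                    "saturated_linear requires saturation_point in (0, 1]"
                )
        elif self.saturation_point is not None:
            raise ProductionConfigError(
                "saturation_point only applies to the saturated_linear relationship"
            )
        if self.schedule not in ("bursty", "steady"):
            raise ProductionConfigError(f"unknown schedule {self.schedule!r}")
        if self.steady_events < 1:
            raise ProductionConfigError("steady_events must be >= 1")
        if not 0 < self.ago_per_sirna <= 1:
            raise ProductionConfigError("ago_per_sirna must lie in (0, 1]")
        if self.loading not in ("proportional", "competitive"):
            raise ProductionConfigError(f"unknown loading mode {self.loading!r}")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # ties round away from zero; x >= 0 here so floor(x + 0.5)
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def production_raw(m: np.ndarray, spec: ProductionSpec) -> np.ndarray:
    """Unrounded siRNA production for methylation fractions ``m`` in [0, 1]."""
    m = np.asarray(m, dtype=float)
    if np.any((m < 0) | (m > 1 + 1e-12)):
        raise ValueError("methylation fractions must lie in [0, 1]")
    if spec.relationship == "linear":
        return m * spec.production_level
    if spec.relationship == "saturated_linear":
        return np.minimum(m, spec.saturation_point) * spec.production_level
    if spec.relationship == "hill":
        x = 100.0 * m
        xh = x**spec.hill_exponent
        return spec.hill_amplitude * xh / (spec.hill_half_max**spec.hill_exponent + xh)
    # sigmoid
    x = 100.0 * m
    return spec.sigmoid_amplitude * x / (spec.sigmoid_half_max + x)


def sirna_counts(m: np.ndarray, spec: ProductionSpec) -> np.ndarray:
    """Vectorised siRNA counts for methylation fractions ``m`` in [0, 1]."""
    return _round_half_away(production_raw(m, spec))


def sirna_count(m: float, spec: ProductionSpec) -> int:
    """siRNAs produced by a single locus at methylation fraction ``m``."""
    return int(sirna_counts(np.array([m]), spec)[0])


def production_schedule(spec: ProductionSpec, cycle_duration: float) -> np.ndarray:
    """Event times (seconds from replication) of siRNA production in one cycle."""
    if cycle_duration <= 0:
        raise ValueError("cycle_duration must be positive")
    if spec.schedule == "bursty":
        return np.array([0.0])
    k = np.arange(spec.steady_events, dtype=float)
    return k * cycle_duration / spec.steady_events


def produce_sirnas(
    chh: np.ndarray,
    spec: ProductionSpec,
    cg: np.ndarray | None = None,
    raw: bool = False,
) -> np.ndarray:
    """Per-locus siRNA additions at one production event.

    Counts are evaluated at the loci's *current* methylation; when
    ``spec.cg_coupled`` the CG fraction is added to the CHH fraction.
    Each siRNA matches only its source locus, so the additions are
    returned as a per-locus count vector (unrounded when ``raw``).
    """
    m = np.asarray(chh, dtype=float)
    if spec.cg_coupled:
        if cg is None:
            raise ProductionConfigError("cg_coupled production requires a CG vector")
        m = np.minimum(m + np.asarray(cg, dtype=float), 1.0)
    return production_raw(m, spec) if raw else sirna_counts(m, spec)


def load_ago(
    pool: np.ndarray, ago_per_sirna: float, rng: np.random.Generator
) -> np.ndarray:
    """Load a limiting AGO pool with siRNAs chosen uniformly without replacement.

    ``pool`` is the vector of source-locus ids of the free siRNAs;
    ``floor(ago_per_sirna * len(pool))`` of them are selected to form
    AGO:siRNA complexes.  Unselected siRNAs are discarded.  Returns the
    target-locus ids of the complexes formed.
    """
    pool = np.asarray(pool)
    n_complex = int(np.floor(ago_per_sirna * pool.size))
    if n_complex == 0:
        return pool[:0]
    if n_complex >= pool.size:
        return pool.copy()
    idx = rng.choice(pool.size, size=n_complex, replace=False)
    return pool[np.sort(idx)]


def allocate_ago(
    raw_production: np.ndarray,
    counts: np.ndarray,
    ago_per_sirna: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Proportional AGO loading: per-locus complex counts.

    Each locus receives ``ago_per_sirna`` AGO proteins per unit of its
    (unrounded) siRNA production, stochastically rounded to an integer
    so the expected allocation is exactly proportional; the allocation
    is capped by the integer number of siRNAs the locus actually
    produced, and a locus producing no siRNAs receives none.
    """
    raw = np.asarray(raw_production, dtype=float)
    counts = np.asarray(counts)
    expected = ago_per_sirna * raw
    base = np.floor(expected)
    frac = expected - base
    alloc = (base + (rng.random(raw.size) < frac)).astype(np.int64)
    alloc = np.minimum(alloc, counts.astype(np.int64))
    alloc[counts == 0] = 0
    return alloc


def halve_pool(targets: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomly retain ``floor(n/2)`` complexes at replication."""
    targets = np.asarray(targets)
    keep = targets.size // 2
    if keep == 0:
        return targets[:0]
    idx = rng.choice(targets.size, size=keep, replace=False)
    return targets[np.sort(idx)]
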