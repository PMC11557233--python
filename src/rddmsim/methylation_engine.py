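"""Generation loop: dwell-driven methylation gain, calibration, replication.

The currency of reinforcement is matched dwell time — the summed
duration of association of all matching AGO:siRNA complexes at a locus
within one cell cycle.  During the first ("burn-in") generation the
model internally estimates ``dwell_per_percent``, the seconds of matched
dwell required to raise CHH methylation by one percentage point, by
assuming the cycle's mean dwell is exactly sufficient for the median
locus to regain what replication removes (half its methylation: with a
median of 8%, a 4-percentage-point gain).  All kinetic parameters
influence realised dwell, so this calibration makes results robust to
the overall time scale of the cycle.  Every generation (including the
burn-in) opens with DNA synthesis — methylation halves and the complex
pool is rebuilt by the post-replication siRNA burst — and closes
pre-replication; from the second generation on, CHH methylation is
updated continuously through the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig
from .locus_init import sample_cg_methylation, sample_initial_methylation
from .sirna_dynamics import (
    allocate_ago,
    halve_pool,
    load_ago,
    produce_sirnas,
    production_schedule,
)
from .target_search import ComplexPopulation, advance

__all__ = [
    "LociState",
    "CalibrationResult",
    "GenerationStats",
    "SimulationResult",
    "CalibrationError",
    "apply_dwell",
    "calibrate_dwell_per_percent",
    "replicate",
    "run_generation",
    "run_simulation",
]


class CalibrationError(RuntimeError):
    """Burn-in produced no matched dwell although siRNAs were made."""


@dataclass
class LociState:
    """Structure-of-arrays state of all RdDM loci."""

    chh: np.ndarray
    cg: np.ndarray | None = None
    occupancy: np.ndarray = None
    cycle_dwell: np.ndarray = None
    occupancy_rejections: np.ndarray = None

    def __post_init__(self) -> None:
        n = self.chh.size
        if self.occupancy is None:
            self.occupancy = np.zeros(n, dtype=np.int64)
        if self.cycle_dwell is None:
            self.cycle_dwell = np.zeros(n, dtype=np.float64)
        if self.occupancy_rejections is None:
            self.occupancy_rejections = np.zeros(n, dtype=np.int64)

    @property
    def n_loci(self) -> int:
        return self.chh.size


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the burn-in dwell calibration.

    ``dwell_per_percent`` is ``reference_dwell / target_gain_pp`` where
    ``reference_dwell`` is the burn-in mean total dwell across loci and
    ``target_gain_pp`` is the percentage-point gain the median locus
    needs to offset replication (100 * initial_median / 2).
    """

    dwell_per_percent: float
    reference_dwell: float
    target_gain_pp: float

    @property
    def disabled(self) -> bool:
        """True when reinforcement is off (no siRNA production)."""
        return not np.isfinite(self.dwell_per_percent)


@dataclass
class GenerationStats:
    """Per-generation record (methylation is end-of-cycle, pre-replication)."""

    generation: int
    methylation: np.ndarray
    pool_size: int
    loci_lost: int
    occupancy_rejections: int
    dwell_per_percent: float
    mean_dwell: float
    locus_dwell: np.ndarray | None = None
    locus_rejections: np.ndarray | None = None
    cg: np.ndarray | None = None


@dataclass
class SimulationResult:
    """Full trajectory of one simulation replicate."""

    config: SimulationConfig
    seed: int
    initial_methylation: np.ndarray
    final_methylation: np.ndarray
    generations: list[GenerationStats]
    calibration: CalibrationResult
    initial_cg: np.ndarray | None = None

    @property
    def first_generation_methylation(self) -> np.ndarray:
        """End-of-burn-in methylation — the stability-test baseline.

        The final (tenth) generation is compared to the first
        generation; both are end-of-cycle, pre-replication vectors, so
        the comparison measures maintenance across the nine subsequent
        cell cycles.
        """
        return self.generations[0].methylation

    def stability_baseline(self, baseline: str = "first_generation") -> np.ndarray:
        if baseline == "first_generation":
            return self.first_generation_methylation
        if baseline == "initial":
            return self.initial_methylation
        raise ValueError(f"unknown stability baseline {baseline!r}")


def apply_dwell(m: float | np.ndarray, dwell, cal: CalibrationResult):
    """Convert matched dwell seconds into CHH methylation gain.

    ``m' = min(1, m + 0.01 * dwell / dwell_per_percent)``; a dwell equal
    to ``dwell_per_percent`` gains exactly one percentage point.
    """
    if cal.disabled:
        return np.minimum(np.asarray(m, dtype=float), 1.0) if np.ndim(m) else min(float(m), 1.0)
    if cal.dwell_per_percent <= 0:
        raise CalibrationError("dwell_per_percent must be positive")
    out = np.asarray(m, dtype=float) + 0.01 * np.asarray(dwell, dtype=float) / cal.dwell_per_percent
    out = np.minimum(out, 1.0)
    return float(out) if np.ndim(m) == 0 else out


def calibrate_dwell_per_percent(
    dwell_totals: np.ndarray,
    initial_median: float,
    post_methylation: np.ndarray | None = None,
    saturation_point: float | None = None,
    exclude: np.ndarray | None = None,
) -> CalibrationResult:
    """Set the dwell-to-methylation exchange rate from burn-in dwell totals.

    The target gain is the amount the median locus loses to replication,
    ``100 * initial_median / 2`` percentage points (4 pp for the 8%
    median case), and the calibration assumes the dwell a locus realises
    is exactly sufficient to regain that loss — i.e. for the median
    locus to double its post-replication methylation.

    When ``post_methylation`` (the halved methylation vector the burn-in
    cycle ran at) is supplied, dwell is regressed through the origin on
    the methylation driving production (capped at ``saturation_point``
    when the production rule saturates):
    ``dwell_per_percent = sum(dwell) / (100 * sum(w))`` with
    ``w = min(post_methylation, saturation)``.  Under the model's
    dwell-proportional-to-production structure this is an unbiased,
    low-noise estimate of the seconds of dwell delivered per percentage
    point of methylation present, and it makes the expected gain of
    every unsaturated locus equal its replication loss.  The reference
    dwell — the expected burn-in dwell of a locus at the median — then
    satisfies ``reference_dwell = dwell_per_percent * target_gain_pp``
    exactly.  Without ``post_methylation`` the reference falls back to
    the mean dwell across all loci.
    """
    dwell_totals = np.asarray(dwell_totals, dtype=float)
    if dwell_totals.size == 0:
        raise CalibrationError("no loci to calibrate on")
    target_gain_pp = 100.0 * initial_median / 2.0
    total = float(dwell_totals.sum())
    if total <= 0:
        raise CalibrationError(
            "burn-in generation accumulated no matched dwell; "
            "cannot calibrate dwell_per_percent"
        )
    if post_methylation is None:
        reference = float(dwell_totals.mean())
        dwell_per_percent = reference / target_gain_pp
    else:
        w = np.asarray(post_methylation, dtype=float)
        if saturation_point is not None:
            w = np.minimum(w, saturation_point)
        d = dwell_totals
        if exclude is not None and 0 < exclude.sum() < exclude.size:
            # occupancy-limited loci realise less dwell than their
            # production predicts and would bias the ratio low
            keep = ~exclude
            w = w[keep]
            d = d[keep]
        denom = 100.0 * float(w.sum())
        if denom <= 0:
            raise CalibrationError("post-replication methylation sums to zero")
        dwell_per_percent = float(d.sum()) / denom
        reference = dwell_per_percent * target_gain_pp
    return CalibrationResult(
        dwell_per_percent=dwell_per_percent,
        reference_dwell=reference,
        target_gain_pp=target_gain_pp,
    )


def replicate(
    loci: LociState, population: ComplexPopulation, rng: np.random.Generator
) -> ComplexPopulation:
    """Apply one replication event.

    Methylation (CHH and CG) halves through DNA synthesis; the
    AGO:siRNA pool is randomly reduced to ``floor(n/2)``; all bound
    complexes release (their fate through replication being unknown,
    none are assumed to persist at their locus) and occupancies and
    cycle dwell reset.
    """
    loci.chh /= 2.0
    if loci.cg is not None:
        loci.cg /= 2.0
    keep_targets = halve_pool(population.target, rng)
    new_pop = ComplexPopulation.from_targets(keep_targets)
    loci.occupancy[:] = 0
    loci.cycle_dwell[:] = 0.0
    loci.occupancy_rejections[:] = 0
    return new_pop


def _event_step_bounds(event_times: np.ndarray, cycle_duration: float, dt: float):
    """Segment the cycle's step grid at the production events."""
    n_total = int(round(cycle_duration / dt))
    starts = [min(int(round(t / dt)), n_total) for t in event_times]
    ends = starts[1:] + [n_total]
    return list(zip(starts, ends))


def run_generation(
    loci: LociState,
    population: ComplexPopulation,
    config: SimulationConfig,
    rng: np.random.Generator,
    generation: int,
    calibration: CalibrationResult | None,
    initial_median: float | None = None,
) -> tuple[ComplexPopulation, GenerationStats, CalibrationResult]:
    """Run one full cell cycle and its closing replication.

    The cycle opens with DNA synthesis: methylation and the complex
    pool halve, then siRNA bursts and the search loop follow, so the
    recorded end-of-generation vector is the pre-replication state of
    the next cycle.  When ``calibration`` is None this is the burn-in
    generation: dwell is accumulated with methylation frozen, the
    calibration is computed from the cycle's dwell log and then applied
    retrospectively to each locus's dwell total.
    """
    spec = config.production
    kin = config.kinetics
    dt = kin.step_interval
    burn_in = calibration is None
    dpp = 0.0 if burn_in else calibration.dwell_per_percent
    if not burn_in and calibration.disabled:
        dpp = 0.0  # reinforcement off: accumulate nothing into methylation

    population = replicate(loci, population, rng)
    if config.pool_policy == "recycle":
        # complexes do not persist past DNA synthesis: their AGO is
        # recycled into the post-replication burst (AGO abundance is
        # coupled to current siRNA production)
        population = ComplexPopulation.from_targets(np.empty(0, dtype=np.int64))
    event_times = production_schedule(spec, config.cycle_duration)
    segments = _event_step_bounds(event_times, config.cycle_duration, dt)
    counts = None
    for event_index, ((start, end), _t) in enumerate(zip(segments, event_times)):
        raw = produce_sirnas(loci.chh, spec, loci.cg, raw=True)
        if spec.schedule == "steady" and not spec.steady_full_production:
            raw = raw / spec.steady_events
        counts = np.floor(raw + 0.5).astype(np.int64)
        if spec.loading == "proportional":
            alloc = allocate_ago(raw, counts, spec.ago_per_sirna, rng)
            new_targets = np.repeat(np.arange(loci.n_loci, dtype=np.int64), alloc)
        else:
            pool = np.repeat(np.arange(loci.n_loci, dtype=np.int64), counts)
            new_targets = load_ago(pool, spec.ago_per_sirna, rng)
            if event_index == 0 and population.size > 0:
                # surviving complexes count against the burst's AGO
                # budget, so only the shortfall is newly loaded
                n_new = max(0, new_targets.size - population.size)
                if n_new < new_targets.size:
                    keep = rng.choice(new_targets.size, size=n_new, replace=False)
                    new_targets = new_targets[np.sort(keep)]
        if new_targets.size:
            population = population.extend(ComplexPopulation.from_targets(new_targets))
        n_steps = end - start
        if n_steps > 0 and population.size > 0:
            advance(
                population, loci, kin, dt=dt, rng=rng,
                n_steps=n_steps, dwell_per_percent=dpp,
            )
    loci_lost = int(np.sum(counts == 0)) if counts is not None else loci.n_loci

    if burn_in:
        if initial_median is None:
            raise ValueError("burn-in generation requires the initial median")
        if population.size == 0 and spec.production_level == 0:
            # reinforcement disabled: pure replication decay
            calibration = CalibrationResult(
                dwell_per_percent=np.inf,
                reference_dwell=0.0,
                target_gain_pp=100.0 * initial_median / 2.0,
            )
        else:
            # loci.chh is still the halved (post-replication) vector here:
            # the burn-in freezes methylation until the calibration exists
            calibration = calibrate_dwell_per_percent(
                loci.cycle_dwell,
                initial_median,
                post_methylation=loci.chh,
                saturation_point=(
                    spec.saturation_point
                    if spec.relationship == "saturated_linear"
                    else None
                ),
                exclude=loci.occupancy_rejections > 0,
            )
            # retrospective application of the burn-in's own dwell log
            loci.chh = np.minimum(
                loci.chh + 0.01 * loci.cycle_dwell / calibration.dwell_per_percent, 1.0
            )

    stats = GenerationStats(
        generation=generation,
        methylation=loci.chh.copy(),
        pool_size=population.size,
        loci_lost=loci_lost,
        occupancy_rejections=int(loci.occupancy_rejections.sum()),
        dwell_per_percent=calibration.dwell_per_percent,
        mean_dwell=float(loci.cycle_dwell.mean()),
        locus_dwell=loci.cycle_dwell.copy(),
        locus_rejections=loci.occupancy_rejections.copy(),
        cg=None if loci.cg is None else loci.cg.copy(),
    )
    return population, stats, calibration


def run_simulation(
    config: SimulationConfig,
    seed: int | None = None,
    progress=None,
) -> SimulationResult:
    """Run one replicate: burn-in plus the remaining generations.

    Generation 1 is the burn-in (included in the ``n_generations``
    total).  The initially assigned vector is a pre-replication state;
    each generation opens with replication and closes pre-replication,
    so the returned final vector (end of the last generation) is
    directly comparable to the initial one for stability testing.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    initial = sample_initial_methylation(config.n_loci, config.initial, rng)
    cg = sample_cg_methylation(config.n_loci, rng) if config.include_cg else None
    initial_median = float(np.median(initial))
    loci = LociState(chh=initial.copy(), cg=None if cg is None else cg.copy())
    population = ComplexPopulation.from_targets(np.empty(0, dtype=np.int64))
    calibration: CalibrationResult | None = None
    stats: list[GenerationStats] = []
    for gen in range(1, config.n_generations + 1):
        population, gen_stats, calibration = run_generation(
            loci, population, config, rng, gen, calibration,
            initial_median=initial_median,
        )
        stats.append(gen_stats)
        if progress is not None:
            progress(gen_stats)
    return SimulationResult(
        config=config,
        seed=seed,
        initial_methylation=initial,
        final_methylation=stats[-1].methylation,
        generations=stats,
        calibration=calibration,
        initial_cg=cg,
    )
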