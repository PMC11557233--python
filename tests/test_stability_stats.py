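"""KS stability scoring, sweep grids and self-inhibition metrics."""

import itertools
import math

import numpy as np
import pytest

from rddmsim.config import SimulationConfig
from rddmsim.methylation_engine import (
    CalibrationResult,
    GenerationStats,
    SimulationResult,
)
from rddmsim.stability_stats import (
    ConditionScore,
    StabilityReport,
    assess_stability,
    ks_two_sample,
    methylation_change,
    score_condition,
    self_inhibition_metrics,
    sweep_summary,
)


def brute_force_ks(a, b):
    """Independent oracle: max |ECDF_a - ECDF_b| over all sample points."""
    points = np.concatenate([a, b])
    best = 0.0
    for x in points:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


def asymptotic_p(d, n, m):
    """Independent oracle: Kolmogorov series with Stephens correction."""
    en = math.sqrt(n * m / (n + m))
    lam = (en + 0.12 + 0.11 / en) * d
    total = 0.0
    for k in range(1, 101):
        total += (-1) ** (k - 1) * math.exp(-2 * k**2 * lam**2)
    return min(max(2 * total, 0.0), 1.0)


class TestKsTwoSample:
    def test_identical_samples(self, rng):
        a = rng.random(40)
        stat, p = ks_two_sample(a, a.copy())
        assert stat == 0.0
        assert p == 1.0

    def test_disjoint_supports(self):
        stat, _ = ks_two_sample([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert stat == 1.0

    def test_statistic_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 51))
            m = int(rng.integers(2, 51))
            a = rng.random(n)
            b = rng.random(m) ** rng.uniform(0.5, 2.0)
            stat, _ = ks_two_sample(a, b)
            assert stat == pytest.approx(brute_force_ks(a, b), abs=1e-12)

    def test_pvalue_matches_series_oracle(self, rng):
        for n, m in [(20, 30), (100, 100), (1000, 1000)]:
            a = rng.normal(size=n)
            b = rng.normal(0.2, size=m)
            stat, p = ks_two_sample(a, b)
            assert p == pytest.approx(asymptotic_p(stat, n, m), abs=1e-6)

    def test_small_sample_fixed_fixture(self):
        stat, _ = ks_two_sample([0.1, 0.2, 0.3, 0.4], [0.15, 0.25, 0.35])
        assert stat == pytest.approx(brute_force_ks(
            np.array([0.1, 0.2, 0.3, 0.4]), np.array([0.15, 0.25, 0.35])
        ))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [0.1])


class TestAssessStability:
    def test_identical_vectors_stable(self, rng):
        v = rng.random(100)
        assert assess_stability(v, v.copy()).stable

    def test_geometric_decay_not_stable(self, rng):
        initial = rng.uniform(0.01, 0.2, 1000)
        report = assess_stability(initial, initial / 2**9)
        assert not report.stable
        assert report.p_value < 1e-6

    def test_alpha_one_never_stable(self, rng):
        v = rng.random(50)
        assert not assess_stability(v, v.copy(), alpha=1.0).stable

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assess_stability(np.zeros(5), np.zeros(6))


class TestScoreCondition:
    def _report(self, stable):
        p = 0.5 if stable else 1e-5
        return StabilityReport(ks_statistic=0.1, p_value=p)

    def test_counting(self):
        flags = [True, True, False, True, False, False, False]
        score = score_condition([self._report(f) for f in flags])
        assert score.n_stable == 3
        assert score.n_replicates == 7

    def test_all_and_none(self):
        assert score_condition([self._report(True)] * 7).n_stable == 7
        assert score_condition([self._report(False)] * 7).n_stable == 0

    def test_permutation_invariance(self):
        flags = [True, False, True, False, False, True, True]
        reports = [self._report(f) for f in flags]
        scores = {
            score_condition(list(perm)).n_stable
            for perm in itertools.permutations(reports)
        }
        assert scores == {4}


class TestSweepSummary:
    def _score(self, level, sat, n_stable, target="RNA", schedule="bursty"):
        return ConditionScore(
            condition={
                "target_type": target,
                "schedule": schedule,
                "saturation_point": sat,
                "production_level": level,
            },
            n_replicates=7,
            n_stable=n_stable,
        )

    def test_single_condition_grid(self):
        grid = sweep_summary([self._score(300, 0.15, 7)])
        assert grid.shape == (1, 1)
        assert grid.loc[("RNA", "bursty", 0.15), 300] == 7

    def test_full_sweep_grid_dimensions(self):
        sats = [0.05, 0.10, 0.15, 0.25, 0.50, None]
        levels = [100, 200, 300, 400, 500, 600, 700]
        scores = [
            self._score(lv, s, 0) for s in sats for lv in levels
        ]
        grid = sweep_summary(scores)
        assert grid.shape == (6, 7)

    def test_cells_pass_through(self):
        grid = sweep_summary([self._score(100, None, 2), self._score(200, None, 5)])
        assert grid.loc[("RNA", "bursty", "none"), 100] == 2
        assert grid.loc[("RNA", "bursty", "none"), 200] == 5

    def test_duplicate_condition_rejected(self):
        with pytest.raises(ValueError):
            sweep_summary([self._score(100, 0.15, 1), self._score(100, 0.15, 2)])


def _fake_result(level, pool, lost, dpp, rejections, n_gens=3):
    cal = CalibrationResult(dwell_per_percent=dpp, reference_dwell=dpp * 4, target_gain_pp=4)
    gens = [
        GenerationStats(
            generation=i + 1,
            methylation=np.full(10, 0.08),
            pool_size=pool,
            loci_lost=lost,
            occupancy_rejections=rejections,
            dwell_per_percent=dpp,
            mean_dwell=100.0,
        )
        for i in range(n_gens)
    ]
    cfg = SimulationConfig(n_loci=10)
    return SimulationResult(
        config=cfg, seed=0, initial_methylation=np.full(10, 0.08),
        final_methylation=np.full(10, 0.08), generations=gens, calibration=cal,
    )


class TestSelfInhibitionMetrics:
    def test_requires_two_levels(self):
        with pytest.raises(ValueError):
            self_inhibition_metrics({100: [_fake_result(100, 10, 0, 1.0, 0)]})

    def test_rows_and_values(self):
        frame = self_inhibition_metrics(
            {
                100: [_fake_result(100, 1000, 5, 10.0, 0)] * 2,
                300: [_fake_result(300, 3000, 1, 30.0, 50)] * 2,
            }
        )
        assert len(frame) == 4
        row = frame[frame.production_level == 300].iloc[0]
        assert row.mean_pool_size == 3000
        assert row.occupancy_rejections == 150  # summed over generations


class TestMethylationChange:
    def test_no_change(self, rng):
        v = rng.random(20)
        deltas, summary = methylation_change(v, v.copy())
        assert np.all(deltas == 0)
        assert summary["mean"] == 0 and summary["variance"] == 0

    def test_summary_values(self):
        deltas, summary = methylation_change(
            np.array([0.1, 0.2, 0.3]), np.array([0.2, 0.2, 0.2])
        )
        assert np.allclose(deltas, [0.1, 0.0, -0.1])
        assert summary["mean"] == pytest.approx(0.0)
        assert summary["variance"] == pytest.approx(0.01)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            methylation_change(np.zeros(3), np.zeros(4))
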