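"""Case-drop bootstrap, CS coefficient, and edge-weight bootstrap intervals."""
import numpy as np
import pandas as pd
import pytest

from bridgenet.estimation import pairwise_pearson, unregularized_network
from bridgenet.centrality import strength
from bridgenet.presets import build_preset
from bridgenet.simulate import simulate
from bridgenet.stability import (
    StabilityReport,
    case_drop_bootstrap,
    cs_coefficient,
    cs_label,
    edge_bootstrap,
)


def _fast_strength(data):
    """Unregularized-estimation strength extractor (fast, fully re-estimated)."""
    return strength(unregularized_network(pairwise_pearson(data))).values()


def _report_from_probs(prob_by_fraction, B=100):
    """Build a report whose per-fraction P(cor >= 0.7) equals given values."""
    fractions = np.array(sorted(prob_by_fraction))
    correlations = {}
    for f, p in prob_by_fraction.items():
        k = int(round(p * B))
        correlations[float(f)] = np.array([1.0] * k + [0.0] * (B - k))
    return StabilityReport(
        drop_fractions=fractions, correlations=correlations, B=B
    )


class TestCsCoefficient:
    def test_all_correlations_one_gives_grid_maximum(self):
        grid = np.round(np.arange(0.05, 0.751, 0.05), 2)
        rep = _report_from_probs({float(f): 1.0 for f in grid})
        assert rep.cs == 0.75

    def test_largest_fraction_meeting_probability(self):
        probs = {round(0.1 * i, 1): 0.99 for i in range(1, 6)}
        probs[0.6] = 0.90
        rep = _report_from_probs(probs)
        assert rep.cs == 0.5
        assert cs_label(rep.cs) == "stable"

    def test_zero_when_no_fraction_qualifies(self):
        rep = _report_from_probs({0.1: 0.5, 0.2: 0.3})
        assert rep.cs == 0.0
        assert rep.label == "unstable"

    def test_monotone_in_threshold_and_probability(self):
        rng = np.random.default_rng(0)
        grid = np.round(np.arange(0.05, 0.751, 0.05), 2)
        correlations = {
            float(f): np.clip(rng.normal(0.9 - f, 0.15, 200), -1, 1) for f in grid
        }
        rep = StabilityReport(drop_fractions=grid, correlations=correlations, B=200)
        for thr_lo, thr_hi in [(0.5, 0.7), (0.7, 0.9)]:
            assert cs_coefficient(rep, thr_hi, 0.95) <= cs_coefficient(rep, thr_lo, 0.95)
        for pl_lo, pl_hi in [(0.8, 0.95), (0.9, 0.99)]:
            assert cs_coefficient(rep, 0.7, pl_hi) <= cs_coefficient(rep, 0.7, pl_lo)

    def test_empty_report_rejected(self):
        rep = _report_from_probs({0.1: 1.0})
        rep.drop_fractions = np.array([])
        with pytest.raises(ValueError, match="empty"):
            cs_coefficient(rep)


class TestCaseDropBootstrap:
    def test_fraction_zero_always_perfect_correlation(self, cognitive_ggm):
        data = simulate(cognitive_ggm, 300, seed=1)
        rep = case_drop_bootstrap(
            data, _fast_strength, fractions=[0.0, 0.1], B=100, seed=2
        )
        assert (rep.correlations[0.0] == 1.0).all()

    def test_constant_statistic_flagged_not_crashed(self, cognitive_ggm):
        data = simulate(cognitive_ggm, 300, seed=1)

        def constant(d):
            return pd.Series(1.0, index=d.node_labels)

        with pytest.warns(UserWarning, match="failed"):
            rep = case_drop_bootstrap(data, constant, fractions=[0.1], B=100, seed=3)
        assert np.isnan(rep.correlations[0.1]).all()
        assert rep.cs == 0.0

    def test_planted_structure_survives_heavy_subsampling(self, cognitive_ggm):
        # regression value from a fixed-seed run of this generator/estimator
        data = simulate(cognitive_ggm, 2000, seed=7)
        rep = case_drop_bootstrap(data, _fast_strength, B=200, seed=7)
        assert rep.cs >= 0.5

    def test_mean_correlation_non_increasing_in_drop_fraction(self, cognitive_ggm):
        data = simulate(cognitive_ggm, 1000, seed=9)
        fractions = [0.1, 0.3, 0.5, 0.7]
        rep = case_drop_bootstrap(data, _fast_strength, fractions=fractions, B=150, seed=4)
        means = [np.nanmean(rep.correlations[f]) for f in fractions]
        assert all(a >= b - 0.02 for a, b in zip(means, means[1:]))

    def test_bootstrap_count_floor(self, cognitive_ggm):
        data = simulate(cognitive_ggm, 300, seed=1)
        with pytest.raises(ValueError, match="at least 100"):
            case_drop_bootstrap(data, _fast_strength, B=10, seed=1)

    def test_seed_reproducibility(self, cognitive_ggm):
        data = simulate(cognitive_ggm, 400, seed=5)
        a = case_drop_bootstrap(data, _fast_strength, fractions=[0.2], B=100, seed=11)
        b = case_drop_bootstrap(data, _fast_strength, fractions=[0.2], B=100, seed=11)
        assert np.array_equal(a.correlations[0.2], b.correlations[0.2])


def _unreg_estimator(data):
    return unregularized_network(pairwise_pearson(data))


class TestEdgeBootstrap:
    def test_interval_width_shrinks_with_n(self, cognitive_ggm):
        widths = {}
        for n in (500, 10_000):
            data = simulate(cognitive_ggm, n, seed=13)
            ci = edge_bootstrap(data, _unreg_estimator, B=150, seed=13)
            lo, hi = ci.interval("Read", "Spell")
            widths[n] = hi - lo
        assert widths[10_000] < widths[500]

    def test_planted_edge_coverage(self, cognitive_ggm):
        # 95% percentile interval contains the planted 0.63 in >= 90% of
        # 20 meta-replicates at the cohort's behavioral sample size
        hits = 0
        for meta in range(20):
            data = simulate(cognitive_ggm, 805, seed=100 + meta)
            ci = edge_bootstrap(data, _unreg_estimator, B=500, seed=200 + meta)
            lo, hi = ci.interval("Read", "Spell")
            hits += lo <= 0.63 <= hi
        assert hits >= 18

    def test_b_floor_rejected(self, cognitive_ggm):
        data = simulate(cognitive_ggm, 300, seed=1)
        with pytest.raises(ValueError, match="at least 100"):
            edge_bootstrap(data, _unreg_estimator, B=10, seed=1)

    def test_monte_carlo_stability_of_cs(self, cognitive_ggm):
        # CS from B=500 vs B=150 differs by at most one grid step
        data = simulate(cognitive_ggm, 1500, seed=21)
        cs = {}
        for B in (150, 500):
            rep = case_drop_bootstrap(data, _fast_strength, B=B, seed=B)
            cs[B] = rep.cs
        assert abs(cs[150] - cs[500]) <= 0.05 + 1e-9
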