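"""Network estimation: pairwise correlations, PSD repair, EBIC-glasso, summaries."""
import warnings

import numpy as np
import pandas as pd
import pytest

from bridgenet.estimation import (
    CorrelationEstimate,
    ebic_glasso,
    edge_summary,
    glasso_precision,
    nearest_psd,
    pairwise_pearson,
    unregularized_network,
)
from bridgenet.ggm import partial_correlations
from bridgenet.simulate import MultilayerDataset, simulate

from .conftest import chain3_ggm, make_net


def _dataset(df):
    return MultilayerDataset(df, {c: "cognition" for c in df.columns})


class TestPairwisePearson:
    def test_identical_complete_columns(self):
        x = np.arange(20.0)
        est = pairwise_pearson(_dataset(pd.DataFrame({"a": x, "b": x, "c": -x})))
        assert est.R[0, 1] == pytest.approx(1.0)
        assert est.R[0, 2] == pytest.approx(-1.0)
        assert (est.Npair == 20).all()
        assert est.n_effective == 20

    def test_pairwise_counts_on_overlapping_blocks(self):
        # a observed on subjects 0..499, b on 400..904: overlap = 100
        n = 905
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        df.loc[500:, "a"] = np.nan
        df.loc[:399, "b"] = np.nan
        est = pairwise_pearson(_dataset(df))
        labels = est.node_labels
        i, j = labels.index("a"), labels.index("b")
        assert est.Npair[i, j] == 100
        assert est.Npair[i, i] == 500
        assert est.n_effective == n

    def test_constant_column_raises_named_error(self):
        df = pd.DataFrame({"a": np.ones(30), "b": np.arange(30.0)})
        with pytest.raises(ValueError, match="'a'"):
            pairwise_pearson(_dataset(df))

    def test_pair_below_floor_raises(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        df.loc[5:, "a"] = np.nan  # only 5 complete pairs
        with pytest.raises(ValueError, match="fewer than"):
            pairwise_pearson(_dataset(df))

    def test_min_pairwise_n_effective_rule(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        df.loc[60:, "c"] = np.nan
        est = pairwise_pearson(_dataset(df), n_effective_rule="min_pairwise")
        assert est.n_effective == 60


class TestNearestPsd:
    def test_psd_input_returned_unchanged(self):
        R = np.array([[1.0, 0.3, 0.0], [0.3, 1.0, 0.2], [0.0, 0.2, 1.0]])
        assert np.abs(nearest_psd(R) - R).max() == 0.0

    def test_indefinite_matrix_repaired(self):
        R = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        assert np.linalg.eigvalsh(R).min() < 0  # genuinely indefinite
        fixed = nearest_psd(R)
        assert np.linalg.eigvalsh(fixed).min() >= 0
        assert np.allclose(np.diag(fixed), 1.0)
        assert np.allclose(fixed, fixed.T)

    def test_identity_unchanged(self):
        assert np.abs(nearest_psd(np.eye(4)) - np.eye(4)).max() == 0.0


def _corr_from_matrix(R, n_eff=1000):
    n = len(R)
    labels = [f"v{i}" for i in range(n)]
    return CorrelationEstimate(
        R=np.asarray(R, float),
        Npair=np.full((n, n), n_eff),
        n_effective=n_eff,
        node_labels=labels,
        layer_of={l: "cognition" for l in labels},
    )


class TestEbicGlasso:
    def test_identity_correlation_gives_empty_network(self):
        net = ebic_glasso(_corr_from_matrix(np.eye(5)))
        assert (net.W == 0).all()
        assert edge_summary(net).n_nonzero == 0

    def test_small_penalty_limit_matches_direct_inversion(self, cognitive_ggm):
        # population correlation matrix: glasso at lambda -> 0 equals the
        # unregularized partial correlations from dense inversion
        R = cognitive_ggm.Sigma
        K = glasso_precision(R, 1e-8, max_iter=500)
        d = np.sqrt(np.diag(K))
        W = -K / np.outer(d, d)
        np.fill_diagonal(W, 0.0)
        assert np.abs(W - cognitive_ggm.P).max() < 1e-4

    def test_chain_support_recovery_at_large_n(self):
        data = simulate(chain3_ggm(), 50_000, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = ebic_glasso(pairwise_pearson(data), gamma=0.5)
        assert net.weight("A", "B") == pytest.approx(0.5, abs=0.05)
        assert net.weight("B", "C") == pytest.approx(0.5, abs=0.05)
        assert abs(net.weight("A", "C")) < 0.01

    def test_monotone_sparsity_along_path(self, cognitive_ggm):
        corr = _corr_from_matrix(cognitive_ggm.Sigma, n_eff=805)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = ebic_glasso(corr)
        counts = net.meta["edge_counts"]
        ok = counts[~np.isnan(counts)]
        # lambda decreases along the path, so edge counts may only grow
        assert (np.diff(ok) >= 0).all()

    def test_support_recovery_on_preset(self, cognitive_ggm):
        # no missed edges with |p| >= 0.05; spurious edges are numerically tiny
        data = simulate(cognitive_ggm, 100_000, seed=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = ebic_glasso(pairwise_pearson(data), gamma=0.5)
        P, W = cognitive_ggm.P, net.W
        strong = np.abs(P) >= 0.05
        assert (np.abs(W)[strong] > 0).all()
        spurious = np.abs(W)[(P == 0) & ~np.eye(len(P), dtype=bool)]
        assert spurious.max() < 0.02

    def test_variable_order_invariance(self, cognitive_ggm):
        data = simulate(cognitive_ggm, 3000, seed=4)
        perm = list(reversed(data.node_labels))
        permuted = data.select(perm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = ebic_glasso(pairwise_pearson(data))
            net_p = ebic_glasso(pairwise_pearson(permuted))
        # coordinate descent visits variables in order, so solutions agree
        # only to solver tolerance under permutation
        for a, b in [("Read", "Spell"), ("NO", "MR"), ("DR", "BDR"), ("Age", "Pea")]:
            assert net.weight(a, b) == pytest.approx(net_p.weight(a, b), abs=1e-3)

    def test_non_psd_input_rejected(self):
        R = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        with pytest.raises(ValueError, match="not PSD"):
            ebic_glasso(_corr_from_matrix(R))


class TestEdgeSummary:
    def test_hand_computed_summary(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.63
        W[0, 2] = W[2, 0] = 0.27
        labels = ["a", "b", "c", "Age"]
        layers = {"a": "cognition", "b": "cognition", "c": "cognition", "Age": "age"}
        net = make_net(W, labels, layers)
        s = edge_summary(net)
        assert s.mean == pytest.approx(0.30)
        assert s.median == pytest.approx(0.27)
        assert (s.min, s.max) == (0.0, 0.63)
        assert s.n_edges == 3

    def test_empty_network_all_zero_summary(self):
        s = edge_summary(make_net(np.zeros((5, 5))))
        assert (s.mean, s.median, s.min, s.max, s.n_nonzero) == (0, 0, 0, 0, 0)

    def test_edges_touching_age_excluded(self):
        W = np.zeros((3, 3))
        W[0, 2] = W[2, 0] = 0.5  # only edge involves age
        labels = ["a", "b", "Age"]
        layers = {"a": "cognition", "b": "cognition", "Age": "age"}
        s = edge_summary(make_net(W, labels, layers))
        assert (s.mean, s.median, s.min, s.max, s.n_nonzero) == (0, 0, 0, 0, 0)

    def test_unregularized_matches_population_at_large_n(self, cognitive_ggm):
        data = simulate(cognitive_ggm, 50_000, seed=6)
        net = unregularized_network(pairwise_pearson(data))
        assert np.abs(net.W - cognitive_ggm.P).max() < 0.03
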