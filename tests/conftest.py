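"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from bridgenet.estimation import PcorNetwork
from bridgenet.ggm import PopulationGGM


def make_net(W, labels=None, layers=None) -> PcorNetwork:
    """Wrap a weight matrix as a PcorNetwork (default: all-cognition layer)."""
    W = np.asarray(W, dtype=float)
    n = len(W)
    labels = labels or [f"v{i}" for i in range(n)]
    layer_of = layers or {l: "cognition" for l in labels}
    return PcorNetwork(W=W, node_labels=list(labels), layer_of=layer_of)


def set_partitions(items):
    """All set partitions (restricted-growth enumeration); oracle helper."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1 :]
        yield [[first]] + smaller


def exhaustive_max_modularity(A: np.ndarray):
    """Brute-force modularity maximum over every partition (n <= 8).

    Independent of the community module: evaluates Newman's formula directly.
    """
    n = len(A)
    two_m = A.sum()
    d = A.sum(axis=1)
    best_q, best_partition = -np.inf, None
    for partition in set_partitions(range(n)):
        q = 0.0
        for block in partition:
            idx = np.array(block)
            q += A[np.ix_(idx, idx)].sum() / two_m - (d[idx].sum() / two_m) ** 2
        if q > best_q:
            best_q, best_partition = q, partition
    return best_q, best_partition


def chain3_ggm() -> PopulationGGM:
    """3-node chain A-B-C with partial correlations 0.5, 0.5 and p(A,C)=0."""
    P = np.array([[0.0, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.0]])
    return PopulationGGM(
        node_labels=("A", "B", "C"),
        layer_of={"A": "cognition", "B": "cognition", "C": "cognition"},
        P=P,
    )


@pytest.fixture(scope="session")
def cognitive_ggm():
    from bridgenet.presets import build_preset

    return build_preset("calm_cognitive")


@pytest.fixture(scope="session")
def cognitive_glasso_net(cognitive_ggm):
    """EBIC-glasso network on a moderate cognitive-layer sample; reused across tests."""
    import warnings

    from bridgenet.estimation import ebic_glasso, pairwise_pearson
    from bridgenet.simulate import simulate

    data = simulate(cognitive_ggm, 2000, seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ebic_glasso(pairwise_pearson(data), gamma=0.5)
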