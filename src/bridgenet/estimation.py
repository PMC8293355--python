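"""Regularized partial-correlation network estimation.

The estimation chain mirrors standard practice in network psychometrics:

1. Pearson correlations with pairwise deletion over incomplete data.
2. Positive-semidefinite repair by eigenvalue clipping (pairwise deletion
   can produce indefinite matrices).
3. Graphical lasso solved along a log-spaced penalty path, with the model
   selected by the extended Bayesian information criterion (EBIC),

       EBIC_gamma = -2 l(K) + E log(n) + 4 E gamma log(p),

   where l(K) = (n/2)(log det K - tr(S K)) is the Gaussian log-likelihood of
   the precision matrix K, E the number of nonzero unique off-diagonal
   precision entries, p the number of nodes, and gamma the density penalty
   (0.5 by default).
4. Conversion of the selected precision matrix to partial correlations
   w_ij = -k_ij / sqrt(k_ii k_jj).

The age column participates in estimation like any other node but is
excluded from edge summaries, mirroring the estimation-versus-reporting
split used for covariate nodes in this literature.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from .ggm import partial_correlations
from .simulate import MultilayerDataset

__all__ = [
    "CorrelationEstimate",
    "PcorNetwork",
    "EdgeSummary",
    "pairwise_pearson",
    "nearest_psd",
    "ebic_glasso",
    "glasso_precision",
    "unregularized_network",
    "edge_summary",
    "edge_list",
    "to_graphml",
]

log = logging.getLogger(__name__)

ZERO_TOL = 1e-10  # |w| below this is stored as a literal zero


@dataclass
class CorrelationEstimate:
    """Pairwise-deletion correlation matrix with per-pair sample sizes."""

    R: np.ndarray
    Npair: np.ndarray
    n_effective: int
    node_labels: list[str]
    layer_of: dict[str, str]


@dataclass
class PcorNetwork:
    """Estimated partial-correlation network with selection metadata."""

    W: np.ndarray
    node_labels: list[str]
    layer_of: dict[str, str]
    lambda_selected: float = 0.0
    gamma: float = 0.5
    lambda_path: np.ndarray = field(default_factory=lambda: np.array([]))
    ebic_path: np.ndarray = field(default_factory=lambda: np.array([]))
    n_effective: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if not np.allclose(W, W.T, atol=1e-8):
            raise ValueError("edge-weight matrix must be symmetric")
        W = (W + W.T) / 2.0
        np.fill_diagonal(W, 0.0)
        W[np.abs(W) < ZERO_TOL] = 0.0
        self.W = W

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def index_of(self, label: str) -> int:
        return self.node_labels.index(label)

    def weight(self, a: str, b: str) -> float:
        return float(self.W[self.index_of(a), self.index_of(b)])

    @property
    def age_included(self) -> bool:
        return any(t == "age" for t in self.layer_of.values())

    def nonage_labels(self) -> list[str]:
        return [l for l in self.node_labels if self.layer_of[l] != "age"]


@dataclass(frozen=True)
class EdgeSummary:
    """Summary of unique off-diagonal edge weights, zeros included, age excluded."""

    mean: float
    median: float
    min: float
    max: float
    n_nonzero: int
    n_edges: int


def pairwise_pearson(
    data: MultilayerDataset,
    min_pair_n: int = 10,
    n_effective_rule: str = "any_observed",
) -> CorrelationEstimate:
    """Pearson correlations from pairwise-complete observations.

    ``n_effective_rule`` is 'any_observed' (subjects with at least one
    observed cell; the default) or 'min_pairwise' (smallest off-diagonal
    pairwise count).
    """
    df = data.values
    labels = list(df.columns)
    obs = df.notna().to_numpy()
    Npair = obs.T.astype(int) @ obs.astype(int)

    for j, col in enumerate(labels):
        col_obs = df[col].dropna()
        if len(col_obs) == 0 or col_obs.std(ddof=1) == 0 or len(col_obs) < 2:
            raise ValueError(f"column {col!r} has zero variance on observed cells")

    low = [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
        if Npair[i, j] < min_pair_n
    ]
    if low:
        raise ValueError(
            f"pairs with fewer than {min_pair_n} complete observations: {low}"
        )

    R = df.corr(method="pearson").to_numpy()
    if np.isnan(R).any():
        bad = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
            if np.isnan(R[i, j])
        ]
        raise ValueError(f"undefined pairwise correlations for pairs: {bad}")
    np.fill_diagonal(R, 1.0)
    R = (R + R.T) / 2.0

    if n_effective_rule == "any_observed":
        n_eff = int(obs.any(axis=1).sum())
    elif n_effective_rule == "min_pairwise":
        off = Npair[~np.eye(len(labels), dtype=bool)]
        n_eff = int(off.min())
    else:
        raise ValueError(f"unknown n_effective_rule {n_effective_rule!r}")
    if n_eff <= len(labels):
        raise ValueError(
            f"effective sample size {n_eff} not larger than node count {len(labels)}"
        )
    return CorrelationEstimate(
        R=R,
        Npair=Npair,
        n_effective=n_eff,
        node_labels=labels,
        layer_of=dict(data.layer_of),
    )


def nearest_psd(R: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Repair an indefinite correlation matrix by eigenvalue clipping.

    Eigenvalues are clipped at ``eig_floor`` and the matrix is rescaled to
    unit diagonal. A matrix that is already PSD is returned unchanged. The
    repair magnitude (largest entrywise change) is logged.
    """
    R = np.asarray(R, dtype=float)
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    eigvals, eigvecs = np.linalg.eigh(R)
    if eigvals[0] >= eig_floor:
        return R
    clipped = np.clip(eigvals, eig_floor, None)
    fixed = (eigvecs * clipped) @ eigvecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    fixed = (fixed + fixed.T) / 2.0
    np.fill_diagonal(fixed, 1.0)
    log.info(
        "nearest_psd: clipped min eigenvalue %.3g; max entry change %.3g",
        eigvals[0],
        np.abs(fixed - R).max(),
    )
    return fixed


def glasso_precision(R: np.ndarray, lam: float, max_iter: int = 200) -> np.ndarray:
    """Graphical lasso precision estimate at a single penalty value.

    Raises on solver non-convergence. As lam -> 0 on a well-conditioned
    matrix this converges to the plain inverse of R.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        _, K = graphical_lasso(np.asarray(R, float), alpha=float(lam), max_iter=max_iter)
    return K


def _precision_to_pcor(K: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2.0


def ebic_glasso(
    corr: CorrelationEstimate,
    gamma: float = 0.5,
    path_size: int = 100,
    min_ratio: float = 0.01,
    post_threshold: float | None = None,
    max_iter: int = 200,
) -> PcorNetwork:
    """Graphical lasso over a penalty path with EBIC model selection.

    The path is log-spaced from lambda_max (the largest absolute off-diagonal
    correlation) down to ``min_ratio * lambda_max``. Penalties where the
    solver fails to converge are skipped with a warning. Ties in EBIC are
    broken toward the sparser (larger-penalty) model.

    ``post_threshold`` optionally zeroes selected edge weights below a fixed
    absolute cutoff after model selection; it is off by default.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    R = np.asarray(corr.R, dtype=float)
    p = len(R)
    eigmin = np.linalg.eigvalsh(R).min()
    if eigmin < -1e-10:
        raise ValueError(
            f"correlation matrix is not PSD (min eigenvalue {eigmin:.3g}); "
            "repair with nearest_psd first"
        )
    n_eff = corr.n_effective
    offdiag = np.abs(R[~np.eye(p, dtype=bool)])
    lam_max = offdiag.max() if offdiag.size else 0.0

    if lam_max < ZERO_TOL:
        return PcorNetwork(
            W=np.zeros((p, p)),
            node_labels=list(corr.node_labels),
            layer_of=dict(corr.layer_of),
            lambda_selected=0.0,
            gamma=gamma,
            n_effective=n_eff,
            meta={"empty_input": True},
        )

    path = np.geomspace(lam_max, min_ratio * lam_max, path_size)
    iu = np.triu_indices(p, k=1)
    best = None  # (ebic, lam, K)
    ebics = np.full(path_size, np.nan)
    edge_counts = np.full(path_size, np.nan)
    skipped: list[float] = []
    for i, lam in enumerate(path):
        try:
            K = glasso_precision(R, lam, max_iter=max_iter)
        except (FloatingPointError, ConvergenceWarning, np.linalg.LinAlgError):
            skipped.append(float(lam))
            continue
        E = int((np.abs(K[iu]) > ZERO_TOL).sum())
        edge_counts[i] = E
        sign, logdet = np.linalg.slogdet(K)
        if sign <= 0:
            skipped.append(float(lam))
            continue
        ll = (n_eff / 2.0) * (logdet - np.trace(R @ K))
        ebic = -2.0 * ll + E * np.log(n_eff) + 4.0 * E * gamma * np.log(p)
        ebics[i] = ebic
        if best is None or ebic < best[0] - 1e-12:
            best = (ebic, float(lam), K)
    if best is None:
        raise RuntimeError("graphical lasso failed to converge at every penalty")
    if skipped:
        warnings.warn(
            f"graphical lasso skipped {len(skipped)}/{path_size} penalties "
            f"(non-convergence), e.g. lambda={skipped[0]:.4g}",
            stacklevel=2,
        )

    W = _precision_to_pcor(best[2])
    W[np.abs(W) < ZERO_TOL] = 0.0
    if post_threshold is not None:
        W[np.abs(W) < post_threshold] = 0.0
    return PcorNetwork(
        W=W,
        node_labels=list(corr.node_labels),
        layer_of=dict(corr.layer_of),
        lambda_selected=best[1],
        gamma=gamma,
        lambda_path=path,
        ebic_path=ebics,
        n_effective=n_eff,
        meta={"skipped_lambdas": skipped, "edge_counts": edge_counts},
    )


def unregularized_network(corr: CorrelationEstimate) -> PcorNetwork:
    """Sample partial correlations by direct inversion (no penalty)."""
    W = partial_correlations(corr.R)
    return PcorNetwork(
        W=W,
        node_labels=list(corr.node_labels),
        layer_of=dict(corr.layer_of),
        lambda_selected=0.0,
        gamma=float("nan"),
        n_effective=corr.n_effective,
        meta={"estimator": "unregularized"},
    )


def edge_summary(net: PcorNetwork) -> EdgeSummary:
    """Mean/median/min/max of unique off-diagonal weights, age excluded.

    Zeros are included in all statistics, matching the reporting convention
    of edge ranges like "0-0.63" that count absent edges as zeros.
    """
    keep = [i for i, l in enumerate(net.node_labels) if net.layer_of[l] != "age"]
    sub = net.W[np.ix_(keep, keep)]
    iu = np.triu_indices(len(keep), k=1)
    vals = sub[iu]
    if vals.size == 0:
        return EdgeSummary(0.0, 0.0, 0.0, 0.0, 0, 0)
    return EdgeSummary(
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        min=float(vals.min()),
        max=float(vals.max()),
        n_nonzero=int((vals != 0).sum()),
        n_edges=int(vals.size),
    )


def edge_list(net: PcorNetwork, include_zeros: bool = False) -> pd.DataFrame:
    """Unique-pair edge list with layer annotations."""
    rows = []
    for i in range(net.n_nodes):
        for j in range(i + 1, net.n_nodes):
            w = net.W[i, j]
            if w == 0 and not include_zeros:
                continue
            a, b = net.node_labels[i], net.node_labels[j]
            rows.append(
                {
                    "node_i": a,
                    "node_j": b,
                    "weight": w,
                    "layer_i": net.layer_of[a],
                    "layer_j": net.layer_of[b],
                }
            )
    return pd.DataFrame(rows, columns=["node_i", "node_j", "weight", "layer_i", "layer_j"])


def to_graphml(net: PcorNetwork, path) -> None:
    import networkx as nx

    G = nx.Graph()
    for label in net.node_labels:
        G.add_node(label, layer=net.layer_of[label])
    for _, row in edge_list(net).iterrows():
        G.add_edge(row["node_i"], row["node_j"], weight=float(row["weight"]))
    nx.write_graphml(G, path)
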