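"""Bootstrap stability diagnostics for centrality orderings and edge weights.

Two resampling schemes:

* **Case-drop bootstrap** (correlation-stability coefficient). For each
  drop fraction f on a grid, subjects are repeatedly dropped without
  replacement, the full estimation pipeline is re-run on the subsample, and
  the subsample centralities are rank-correlated (Spearman by default) with
  the full-sample ones. The CS coefficient is the largest grid fraction at
  which the empirical probability of a correlation >= 0.7 is at least 0.95.
  CS >= 0.5 is conventionally read as stable, >= 0.25 as moderate.

* **Nonparametric edge bootstrap.** Subjects are resampled with
  replacement, the network re-estimated per replicate, and percentile
  (2.5%, 97.5%) intervals reported per edge.

Replicates where estimation fails (or where the correlation is undefined,
e.g. constant centralities) are flagged and counted as below-threshold
rather than discarded, so estimation failures can only lower CS.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MultilayerDataset

__all__ = [
    "StabilityReport",
    "EdgeCITable",
    "default_drop_fractions",
    "case_drop_bootstrap",
    "cs_coefficient",
    "cs_label",
    "edge_bootstrap",
]

MIN_BOOTSTRAPS = 100


def default_drop_fractions() -> np.ndarray:
    """The default case-drop grid: 0.05 to 0.75 in steps of 0.05."""
    return np.round(np.arange(0.05, 0.751, 0.05), 2)


def cs_label(cs: float) -> str:
    if cs >= 0.5:
        return "stable"
    if cs >= 0.25:
        return "moderate"
    return "unstable"


@dataclass
class StabilityReport:
    """Per-fraction bootstrap correlation samples and the CS coefficient."""

    drop_fractions: np.ndarray
    correlations: dict[float, np.ndarray]  # NaN marks a failed replicate
    B: int
    cor_threshold: float = 0.7
    prob_level: float = 0.95
    cs: float = field(init=False)
    label: str = field(init=False)

    def __post_init__(self) -> None:
        self.cs = cs_coefficient(self, self.cor_threshold, self.prob_level)
        self.label = cs_label(self.cs)

    def retain_probability(self, cor_threshold: float | None = None) -> pd.Series:
        """Empirical P(correlation >= threshold) per drop fraction."""
        thr = self.cor_threshold if cor_threshold is None else cor_threshold
        probs = {}
        for f in self.drop_fractions:
            cors = self.correlations[float(f)]
            probs[float(f)] = float(np.mean(np.nan_to_num(cors, nan=-np.inf) >= thr))
        return pd.Series(probs, name="retain_probability")

    def n_failed(self) -> dict[float, int]:
        return {
            float(f): int(np.isnan(self.correlations[float(f)]).sum())
            for f in self.drop_fractions
        }

    def to_dict(self) -> dict:
        return {
            "cs": self.cs,
            "label": self.label,
            "B": self.B,
            "cor_threshold": self.cor_threshold,
            "prob_level": self.prob_level,
            "drop_fractions": [float(f) for f in self.drop_fractions],
            "retain_probability": self.retain_probability().to_dict(),
            "n_failed": self.n_failed(),
            "correlation_quantiles": {
                float(f): {
                    q: float(np.nanquantile(self.correlations[float(f)], q))
                    if not np.all(np.isnan(self.correlations[float(f)]))
                    else None
                    for q in (0.025, 0.5, 0.975)
                }
                for f in self.drop_fractions
            },
        }


def cs_coefficient(
    report: StabilityReport, cor_threshold: float = 0.7, prob_level: float = 0.95
) -> float:
    """Largest grid fraction whose empirical P(cor >= threshold) >= prob_level.

    Returns 0 if no fraction qualifies. Failed replicates (NaN) count as
    below threshold.
    """
    if not len(report.drop_fractions):
        raise ValueError("stability report has an empty drop-fraction grid")
    probs = report.retain_probability(cor_threshold)
    ok = [f for f, p in probs.items() if p >= prob_level]
    return float(max(ok)) if ok else 0.0


def _correlate(full: pd.Series, sub: pd.Series, method: str) -> float:
    common = full.index.intersection(sub.index)
    x, y = full.loc[common].to_numpy(), sub.loc[common].to_numpy()
    if len(common) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    if method == "spearman":
        r = stats.spearmanr(x, y).statistic
    elif method == "pearson":
        r = stats.pearsonr(x, y).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r) if np.isfinite(r) else np.nan


def case_drop_bootstrap(
    data: MultilayerDataset,
    statistic,
    fractions=None,
    B: int = 1000,
    seed: int = 0,
    method: str = "spearman",
    cor_threshold: float = 0.7,
    prob_level: float = 0.95,
) -> StabilityReport:
    """Case-drop bootstrap of a per-node statistic.

    ``statistic`` maps a :class:`MultilayerDataset` to a pandas Series of
    per-node values (re-running estimation, and community detection for
    bridge strength, on each subsample). Fraction f drops ceil(f*n) subjects
    uniformly without replacement.
    """
    if B < MIN_BOOTSTRAPS:
        raise ValueError(f"B must be at least {MIN_BOOTSTRAPS}, got {B}")
    fractions = (
        default_drop_fractions() if fractions is None else np.asarray(fractions, float)
    )
    full = statistic(data)
    n = data.n_subjects
    rng = np.random.default_rng(seed)
    correlations: dict[float, np.ndarray] = {}
    for f in fractions:
        f = float(f)
        cors = np.full(B, np.nan)
        n_drop = math.ceil(f * n)
        for b in range(B):
            if n_drop == 0:
                cors[b] = 1.0
                continue
            keep = rng.choice(n, size=n - n_drop, replace=False)
            keep.sort()
            try:
                sub = statistic(data.subset_subjects(keep))
                cors[b] = _correlate(full, sub, method)
            except Exception:
                cors[b] = np.nan
        fail_rate = np.mean(np.isnan(cors))
        if fail_rate > 0.2:
            warnings.warn(
                f"{fail_rate:.0%} of replicates failed at drop fraction {f}",
                stacklevel=2,
            )
        correlations[f] = cors
    return StabilityReport(
        drop_fractions=fractions,
        correlations=correlations,
        B=B,
        cor_threshold=cor_threshold,
        prob_level=prob_level,
    )


@dataclass
class EdgeCITable:
    """Percentile bootstrap confidence intervals per edge."""

    table: pd.DataFrame  # node_i, node_j, estimate, lower, upper
    B: int
    n_failed: int = 0

    def interval(self, a: str, b: str) -> tuple[float, float]:
        t = self.table
        row = t[((t.node_i == a) & (t.node_j == b)) | ((t.node_i == b) & (t.node_j == a))]
        if row.empty:
            raise KeyError(f"no edge {a!r}-{b!r} in table")
        return float(row.lower.iloc[0]), float(row.upper.iloc[0])


def edge_bootstrap(
    data: MultilayerDataset,
    estimator,
    B: int = 1000,
    seed: int = 0,
    ci: tuple[float, float] = (0.025, 0.975),
) -> EdgeCITable:
    """Nonparametric bootstrap CIs for edge weights.

    ``estimator`` maps a dataset to a :class:`~bridgenet.estimation.PcorNetwork`.
    Subjects are resampled with replacement; failed replicates are dropped
    from the interval computation and counted.
    """
    if B < MIN_BOOTSTRAPS:
        raise ValueError(f"B must be at least {MIN_BOOTSTRAPS}, got {B}")
    net = estimator(data)
    labels = net.node_labels
    p = len(labels)
    iu = np.triu_indices(p, k=1)
    point = net.W[iu]
    n = data.n_subjects
    rng = np.random.default_rng(seed)
    draws = np.full((B, len(point)), np.nan)
    n_failed = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            bnet = estimator(data.subset_subjects(idx))
            if bnet.node_labels != labels:
                raise ValueError("replicate returned different node set")
            draws[b] = bnet.W[iu]
        except Exception:
            n_failed += 1
    if n_failed > 0.2 * B:
        warnings.warn(f"{n_failed}/{B} bootstrap replicates failed", stacklevel=2)
    ok = draws[~np.isnan(draws).any(axis=1)]
    if len(ok) == 0:
        raise RuntimeError("every bootstrap replicate failed")
    lower = np.quantile(ok, ci[0], axis=0)
    upper = np.quantile(ok, ci[1], axis=0)
    table = pd.DataFrame(
        {
            "node_i": [labels[i] for i in iu[0]],
            "node_j": [labels[j] for j in iu[1]],
            "estimate": point,
            "lower": lower,
            "upper": upper,
        }
    )
    return EdgeCITable(table=table, B=B, n_failed=n_failed)
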