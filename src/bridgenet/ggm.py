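"""Population Gaussian graphical models defined by partial-correlation matrices.

A Gaussian graphical model (GGM) is parameterized here by its partial
correlation matrix P: the correlation between each pair of variables after
conditioning on all remaining variables. For a precision matrix K,

    pcor_ij = -k_ij / sqrt(k_ii * k_jj)        (i != j)

so a planted P determines a precision matrix up to diagonal scaling, and
hence a unique unit-variance covariance Sigma. These population objects are
the ground truth that the synthetic-data generator samples from and that the
estimators are validated against.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationGGM",
    "pcor_to_covariance",
    "partial_correlations",
]

LAYER_TAGS = ("cognition", "grey", "white", "age")


def _check_pcor_matrix(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("partial-correlation matrix must be square")
    if not np.allclose(P, P.T, atol=1e-12):
        raise ValueError("partial-correlation matrix must be symmetric")
    if not np.allclose(np.diag(P), 0.0, atol=1e-12):
        raise ValueError("partial-correlation matrix must have zero diagonal")
    if np.any(np.abs(P) >= 1.0):
        raise ValueError("all partial correlations must satisfy |p| < 1")
    return P


def pcor_to_covariance(P: np.ndarray) -> np.ndarray:
    """Convert a partial-correlation matrix to the implied unit-variance covariance.

    The standardized precision K = I - P (off-diagonal entries -p_ij) is
    inverted and rescaled to unit variances. Inverting the result and applying
    the pcor identity reproduces P exactly.

    Raises
    ------
    ValueError
        If the implied precision is not positive definite; the message names
        the offending (smallest) eigenvalue.
    """
    P = _check_pcor_matrix(P)
    K = np.eye(len(P)) - P
    eigvals = np.linalg.eigvalsh(K)
    if eigvals[0] <= 0:
        raise ValueError(
            "implied precision matrix is not positive definite "
            f"(smallest eigenvalue {eigvals[0]:.6g})"
        )
    Sigma = np.linalg.inv(K)
    d = np.sqrt(np.diag(Sigma))
    Sigma = Sigma / np.outer(d, d)
    return (Sigma + Sigma.T) / 2.0


def partial_correlations(Sigma: np.ndarray) -> np.ndarray:
    """Exact partial correlations of a covariance matrix via precision inversion.

    Returns a symmetric matrix with zero diagonal. This is the unregularized
    estimator: applied to a sample covariance it gives the sample partial
    correlations, applied to a population covariance it recovers the
    population network.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    K = np.linalg.inv(Sigma)
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    return (P + P.T) / 2.0


@dataclass(frozen=True)
class PopulationGGM:
    """A planted population partial-correlation network.

    Parameters
    ----------
    node_labels : list of variable names.
    layer_of : mapping node -> layer tag ('cognition' | 'grey' | 'white' | 'age').
    P : symmetric partial-correlation matrix, zero diagonal.

    The implied unit-variance covariance ``Sigma`` is computed on
    construction and cached.
    """

    node_labels: tuple[str, ...]
    layer_of: dict[str, str]
    P: np.ndarray
    Sigma: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        labels = tuple(self.node_labels)
        object.__setattr__(self, "node_labels", labels)
        P = _check_pcor_matrix(self.P)
        if len(labels) != len(P):
            raise ValueError("node_labels length must match matrix size")
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be unique")
        missing = [l for l in labels if l not in self.layer_of]
        if missing:
            raise ValueError(f"layer_of does not cover nodes: {missing}")
        extra = [l for l in self.layer_of if l not in labels]
        if extra:
            raise ValueError(f"layer_of names unknown nodes: {extra}")
        bad = {l: t for l, t in self.layer_of.items() if t not in LAYER_TAGS}
        if bad:
            raise ValueError(f"unknown layer tags: {bad}")
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "Sigma", pcor_to_covariance(P))

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def index_of(self, label: str) -> int:
        return self.node_labels.index(label)

    def entry(self, a: str, b: str) -> float:
        """Population partial correlation between two named nodes."""
        return float(self.P[self.index_of(a), self.index_of(b)])

    def nodes_in_layer(self, tag: str) -> list[str]:
        return [l for l in self.node_labels if self.layer_of[l] == tag]
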