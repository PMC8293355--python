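"""Strength and bridge-strength centrality with the 1-SD classification rule.

Strength centrality is the sum of absolute edge weights incident to a node.
Bridge strength restricts that sum to edges crossing community boundaries of
a pre-assigned partition, so for any partition

    strength = bridge strength + within-community strength

holds exactly for every node. Nodes are z-scored (sample SD, n-1) over the
non-age nodes and classified as central when z >= +1; negative z-scores are
computed but never flagged. The age node contributes to the sums but is
excluded from normalization and from the reported tables.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import PcorNetwork

__all__ = ["CentralityTable", "BridgeTable", "strength", "bridge_strength"]


@dataclass
class CentralityTable:
    """Per-node strength, z-score and centrality flag (age excluded)."""

    table: pd.DataFrame
    normalized_nodes: list[str] = field(default_factory=list)

    def values(self, column: str = "strength") -> pd.Series:
        return self.table[column]

    @property
    def central_nodes(self) -> list[str]:
        flagged = self.table[self.table["central"]]
        return list(flagged.sort_values("z", ascending=False).index)


@dataclass
class BridgeTable(CentralityTable):
    assignment: dict[str, int] = field(default_factory=dict)

    def values(self, column: str = "bridge_strength") -> pd.Series:
        return self.table[column]


def _zscore_and_flag(table: pd.DataFrame, column: str) -> pd.DataFrame:
    vals = table[column]
    sd = vals.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        table["z"] = 0.0
    else:
        table["z"] = (vals - vals.mean()) / sd
    table["central"] = table["z"] >= 1.0
    return table


def strength(net: PcorNetwork) -> CentralityTable:
    """Absolute-strength centrality: s_i = sum_j |w_ij| over all neighbors.

    Edges to the age node count toward the sums; the age node itself is
    excluded from the reported table and from the z-normalization.
    """
    nonage = net.nonage_labels()
    if len(nonage) < 3:
        raise ValueError(
            f"need at least 3 non-age nodes to z-score centralities, got {len(nonage)}"
        )
    s = np.abs(net.W).sum(axis=1)
    table = pd.DataFrame(
        {
            "layer": [net.layer_of[l] for l in net.node_labels],
            "strength": s,
        },
        index=pd.Index(net.node_labels, name="node"),
    ).loc[nonage]
    table = _zscore_and_flag(table, "strength")
    return CentralityTable(table=table, normalized_nodes=nonage)


def bridge_strength(net: PcorNetwork, partition) -> BridgeTable:
    """Bridge-strength centrality under a pre-assigned community partition.

    b_i sums |w_ij| over neighbors j assigned to a different community than
    i. The partition must cover every node of the network; singleton
    communities are permitted. A single-community partition yields all-zero
    bridge strengths and a warning.
    """
    assignment = getattr(partition, "assignment", partition)
    missing = [l for l in net.node_labels if l not in assignment]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing}")
    if len(set(assignment[l] for l in net.node_labels)) == 1:
        warnings.warn(
            "partition has a single community: all bridge strengths are zero",
            stacklevel=2,
        )
    nonage = net.nonage_labels()
    if len(nonage) < 3:
        raise ValueError(
            f"need at least 3 non-age nodes to z-score centralities, got {len(nonage)}"
        )
    comm = np.array([assignment[l] for l in net.node_labels])
    cross = comm[:, None] != comm[None, :]
    b = (np.abs(net.W) * cross).sum(axis=1)
    table = pd.DataFrame(
        {
            "layer": [net.layer_of[l] for l in net.node_labels],
            "community": comm,
            "bridge_strength": b,
        },
        index=pd.Index(net.node_labels, name="node"),
    ).loc[nonage]
    table = _zscore_and_flag(table, "bridge_strength")
    return BridgeTable(
        table=table,
        normalized_nodes=nonage,
        assignment={l: int(assignment[l]) for l in net.node_labels},
    )
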