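"""Strength-based connectivity metrics and feature-set assembly.

Seven parameters per subject graph: nodal strength, nodal and network-level
within-network score, inter-network score and within/inter ratio.  "Score"
means the mean surviving (nonzero) edge weight over the relevant edge set:
within-network edges for the within score, boundary-crossing edges for the
inter score.  The ratio indexes network segregation.

Four named feature sets mirror the benchmark's feature-set axis: with
P nodes and K networks they have 3K (network_level), P+3K
(strength_plus_network), 3P (nodal_only) and 4P+3K (all) columns — 21, 421,
1,200 and 1,621 at P=400, K=7.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .graph import AdjacencyMatrix
from .synth import ParcellationSpec

logger = logging.getLogger(__name__)

FEATURE_SETS = ("network_level", "strength_plus_network", "nodal_only", "all")

__all__ = [
    "FEATURE_SETS",
    "node_strength",
    "within_inter_metrics",
    "ratio_scores",
    "assemble_features",
    "feature_count",
    "feature_table",
    "StrengthFeatures",
]


def _weights(adj: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    w = adj.w if isinstance(adj, AdjacencyMatrix) else np.asarray(adj, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("adjacency must be square")
    return w


def node_strength(adj: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    """Per-node sum of incident edge weights."""
    return _weights(adj).sum(axis=1)


def within_inter_metrics(
    adj: AdjacencyMatrix | np.ndarray,
    partition: ParcellationSpec,
    level: str = "nodal",
) -> tuple[np.ndarray, np.ndarray]:
    """Within- and inter-network scores at nodal or network level.

    nodal:   within_i = sum of i's same-network weights / # of i's nonzero
             same-network edges; inter_i analogous over cross-network edges.
    network: within_A = mean nonzero weight over unordered within-A edges;
             inter_A  = mean nonzero weight over edges with exactly one
             endpoint in A.
    Empty denominators yield 0 (logged).
    """
    w = _weights(adj)
    P = w.shape[0]
    if partition.node_count != P:
        raise ValueError("partition does not cover the adjacency's nodes")
    labels = partition.labels
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    cross = labels[:, None] != labels[None, :]
    exists = w > 0

    def _mean(sums: np.ndarray, counts: np.ndarray, what: str) -> np.ndarray:
        out = np.zeros_like(sums, dtype=float)
        nz = counts > 0
        out[nz] = sums[nz] / counts[nz]
        if (~nz).any():
            logger.info("%s: %d empty denominators set to 0", what, int((~nz).sum()))
        return out

    if level == "nodal":
        within = _mean(
            (w * same).sum(axis=1), (exists & same).sum(axis=1), "nodal within"
        )
        inter = _mean(
            (w * cross).sum(axis=1), (exists & cross).sum(axis=1), "nodal inter"
        )
        return within, inter
    if level == "network":
        K = partition.network_count
        within = np.zeros(K)
        inter = np.zeros(K)
        for a in range(1, K + 1):
            in_a = labels == a
            block = w[np.ix_(in_a, in_a)]
            mask = block > 0
            n_within = int(np.triu(mask, 1).sum())
            within[a - 1] = np.triu(block, 1).sum() / n_within if n_within else 0.0
            bound = w[np.ix_(in_a, ~in_a)]
            n_inter = int((bound > 0).sum())
            inter[a - 1] = bound.sum() / n_inter if n_inter else 0.0
            if n_within == 0 or n_inter == 0:
                logger.info("network %d: empty within/inter denominator -> 0", a)
        return within, inter
    raise ValueError(f"unknown level {level!r}")


def ratio_scores(within: np.ndarray, inter: np.ndarray) -> np.ndarray:
    """Within/inter segregation ratio; 0 where inter is 0 (logged)."""
    within = np.asarray(within, dtype=float)
    inter = np.asarray(inter, dtype=float)
    if within.shape != inter.shape:
        raise ValueError("within and inter must have matching lengths")
    out = np.zeros_like(within)
    nz = inter > 0
    out[nz] = within[nz] / inter[nz]
    if (~nz & (within > 0)).any():
        logger.info(
            "ratio: %d entries with inter=0 set to 0", int((~nz & (within > 0)).sum())
        )
    return out


def _feature_names(P: int, K: int, set_id: str) -> list[str]:
    nodal = lambda m: [f"{m}_node{j + 1:03d}" for j in range(P)]
    net = lambda m: [f"{m}_net{a + 1}" for a in range(K)]
    blocks = {
        "network_level": net("net_within") + net("net_inter") + net("net_ratio"),
        "strength_plus_network": nodal("strength")
        + net("net_within")
        + net("net_inter")
        + net("net_ratio"),
        "nodal_only": nodal("nodal_within") + nodal("nodal_inter") + nodal("nodal_ratio"),
        "all": nodal("strength")
        + nodal("nodal_within")
        + nodal("nodal_inter")
        + nodal("nodal_ratio")
        + net("net_within")
        + net("net_inter")
        + net("net_ratio"),
    }
    if set_id not in blocks:
        raise ValueError(f"unknown feature set {set_id!r}")
    return blocks[set_id]


def feature_count(P: int, K: int, set_id: str) -> int:
    return len(_feature_names(P, K, set_id))


def assemble_features(
    adj: AdjacencyMatrix | np.ndarray,
    partition: ParcellationSpec,
    set_id: str = "all",
) -> pd.Series:
    """One subject's feature row in the fixed deterministic order
    (nodal strength, nodal within, nodal inter, nodal ratio, network
    within, network inter, network ratio; subsetted per ``set_id``)."""
    if set_id not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {set_id!r}")
    nw, ni = within_inter_metrics(adj, partition, level="nodal")
    Nw, Ni = within_inter_metrics(adj, partition, level="network")
    parts = {
        "network_level": [Nw, Ni, ratio_scores(Nw, Ni)],
        "strength_plus_network": [node_strength(adj), Nw, Ni, ratio_scores(Nw, Ni)],
        "nodal_only": [nw, ni, ratio_scores(nw, ni)],
        "all": [
            node_strength(adj),
            nw,
            ni,
            ratio_scores(nw, ni),
            Nw,
            Ni,
            ratio_scores(Nw, Ni),
        ],
    }[set_id]
    names = _feature_names(partition.node_count, partition.network_count, set_id)
    return pd.Series(np.concatenate(parts), index=names, name=set_id)


def feature_table(
    adjacencies: list[AdjacencyMatrix | np.ndarray],
    partition: ParcellationSpec,
    set_id: str = "all",
    subject_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Subjects x features table for one feature set."""
    rows = [assemble_features(a, partition, set_id) for a in adjacencies]
    table = pd.DataFrame(rows)
    table.index = subject_ids or [f"sub-{i + 1:04d}" for i in range(len(rows))]
    table.attrs["set_id"] = set_id
    return table


class StrengthFeatures(BaseEstimator, TransformerMixin):
    """Transformer: list of adjacency matrices -> feature DataFrame."""

    def __init__(self, partition: ParcellationSpec = None, set_id: str = "all"):
        self.partition = partition
        self.set_id = set_id

    def fit(self, X, y=None):
        if self.partition is None:
            raise ValueError("a partition is required")
        return self

    def transform(self, X) -> pd.DataFrame:
        return feature_table(X, self.partition, self.set_id)
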