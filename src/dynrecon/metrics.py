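"""Recruitment and integration coefficients from an allegiance matrix.

Node recruitment is the mean allegiance of a node with the members of its
own network (the self term P_ii = 1 is included, as the defining average
runs over the whole network). Node integration is the mean allegiance with
all nodes outside the network. Network-level values are unweighted node
means; pairwise network integration is the mean allegiance over all
cross-network node pairs.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .community import AllegianceMatrix
from .partition import NodePartition

__all__ = [
    "node_recruitment",
    "node_integration",
    "network_recruitment",
    "network_integration",
    "pairwise_network_integration",
    "metric_table",
    "node_metric_table",
]


def _check(P: AllegianceMatrix, part: NodePartition) -> np.ndarray:
    M = P.P
    if M.shape[0] != part.n_nodes:
        raise ValueError(
            f"allegiance has {M.shape[0]} nodes, partition has {part.n_nodes}"
        )
    if P.node_ids is not None and tuple(P.node_ids) != part.nodes:
        missing = set(part.nodes) - set(P.node_ids)
        raise ValueError(f"nodes missing from allegiance matrix: {sorted(missing)}")
    return M


def node_recruitment(P: AllegianceMatrix, part: NodePartition) -> np.ndarray:
    """R_i = (1/m_N) * sum_{j in N(i)} P_ij, for every analysed node i."""
    M = _check(P, part)
    out = np.empty(part.n_nodes, dtype=float)
    for net in part.networks:
        idx = part.indices_of(net)
        out[idx] = M[np.ix_(idx, idx)].mean(axis=1)
    return out


def node_integration(P: AllegianceMatrix, part: NodePartition) -> np.ndarray:
    """I_i = (1/(K - m_N)) * sum_{j not in N(i)} P_ij."""
    M = _check(P, part)
    K = part.n_nodes
    out = np.empty(K, dtype=float)
    for net in part.networks:
        idx = part.indices_of(net)
        if idx.size == K:
            raise ValueError(
                f"network {net!r} contains all nodes; integration undefined"
            )
        other = np.setdiff1d(np.arange(K), idx)
        out[idx] = M[np.ix_(idx, other)].mean(axis=1)
    return out


def network_recruitment(P: AllegianceMatrix, part: NodePartition) -> dict:
    """Unweighted mean of node recruitment over each network's members."""
    r = node_recruitment(P, part)
    return {net: float(r[part.indices_of(net)].mean()) for net in part.networks}


def network_integration(P: AllegianceMatrix, part: NodePartition) -> dict:
    """Unweighted mean of node integration over each network's members."""
    v = node_integration(P, part)
    return {net: float(v[part.indices_of(net)].mean()) for net in part.networks}


def pairwise_network_integration(P: AllegianceMatrix, part: NodePartition) -> dict:
    """Mean allegiance over cross-network node pairs, for every unordered
    pair of distinct networks. Keys are sorted 2-tuples of labels."""
    M = _check(P, part)
    out = {}
    for net_a, net_b in combinations(part.networks, 2):
        ia, ib = part.indices_of(net_a), part.indices_of(net_b)
        key = tuple(sorted((net_a, net_b)))
        out[key] = float(M[np.ix_(ia, ib)].mean())
    return out


def metric_table(subject_id: str, P: AllegianceMatrix,
                 part: NodePartition) -> pd.DataFrame:
    """Tidy per-subject table of the 9 + 36 network-level coefficients.

    Columns: subject_id, metric_type, network_1, network_2 (empty string for
    recruitment rows), value.
    """
    rows = []
    for net, val in network_recruitment(P, part).items():
        rows.append((subject_id, "recruitment", net, "", val))
    for (a, b), val in pairwise_network_integration(P, part).items():
        rows.append((subject_id, "integration", a, b, val))
    return pd.DataFrame(
        rows, columns=["subject_id", "metric_type", "network_1", "network_2",
                       "value"],
    )


def node_metric_table(subject_id: str, P: AllegianceMatrix,
                      part: NodePartition) -> pd.DataFrame:
    """Per-node recruitment and integration values for ROI-level follow-up."""
    r = node_recruitment(P, part)
    i = node_integration(P, part)
    nodes = part.nodes
    nets = [part.network_of[n] for n in nodes]
    rec = pd.DataFrame({
        "subject_id": subject_id, "metric_type": "recruitment",
        "node_id": nodes, "network": nets, "value": r,
    })
    intg = pd.DataFrame({
        "subject_id": subject_id, "metric_type": "integration",
        "node_id": nodes, "network": nets, "value": i,
    })
    return pd.concat([rec, intg], ignore_index=True)
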