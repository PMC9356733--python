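"""Node-to-network partition handling.

A :class:`NodePartition` maps every analysed node to exactly one functional
network label and records nodes excluded from analysis (e.g. cerebellar
parcels). All downstream metrics are defined relative to this partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["NodePartition", "default_partition", "demo_partition"]


@dataclass(frozen=True)
class NodePartition:
    """An ordered node set with network labels and an exclusion set.

    Parameters
    ----------
    node_ids : tuple of str
        All node identifiers in file/table order (including excluded ones).
    network_of : dict
        Maps each non-excluded node id to its network label.
    excluded : frozenset of str
        Node ids excluded from the analysis set.
    """

    node_ids: tuple
    network_of: dict
    excluded: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node ids in partition")
        for n in self.nodes:
            if n not in self.network_of:
                raise ValueError(f"node {n!r} has no network label")
        for net, size in self.sizes.items():
            if size < 2:
                raise ValueError(f"network {net!r} has size {size} < 2")

    @property
    def nodes(self) -> tuple:
        """Non-excluded node ids, in original order."""
        return tuple(n for n in self.node_ids if n not in self.excluded)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def networks(self) -> tuple:
        """Network labels in order of first appearance among analysed nodes."""
        seen = []
        for n in self.nodes:
            lab = self.network_of[n]
            if lab not in seen:
                seen.append(lab)
        return tuple(seen)

    @property
    def sizes(self) -> dict:
        out = {}
        for n in self.nodes:
            lab = self.network_of[n]
            out[lab] = out.get(lab, 0) + 1
        return out

    def indices_of(self, network: str) -> np.ndarray:
        """Positional indices (into ``self.nodes``) of a network's members."""
        if network not in self.sizes:
            raise KeyError(f"unknown network {network!r}")
        return np.array(
            [i for i, n in enumerate(self.nodes) if self.network_of[n] == network],
            dtype=np.intp,
        )

    def labels_array(self) -> np.ndarray:
        """Integer network codes per analysed node (codes index ``networks``)."""
        code = {net: k for k, net in enumerate(self.networks)}
        return np.array([code[self.network_of[n]] for n in self.nodes], dtype=np.intp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": list(self.node_ids),
                "network": [
                    self.network_of.get(n, "") if n not in self.excluded else
                    self.network_of.get(n, "excluded")
                    for n in self.node_ids
                ],
                "excluded": [int(n in self.excluded) for n in self.node_ids],
            }
        )


def from_frame(df: pd.DataFrame) -> NodePartition:
    """Build a partition from a table with node_id / network / excluded columns."""
    required = {"node_id", "network", "excluded"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"partition table missing columns: {sorted(missing)}")
    ids = [str(v) for v in df["node_id"]]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate node ids: {dupes}")
    excluded = frozenset(
        i for i, flag in zip(ids, df["excluded"]) if bool(int(flag))
    )
    network_of = {}
    for i, net in zip(ids, df["network"]):
        if i in excluded:
            continue
        if not isinstance(net, str) or not net.strip():
            raise ValueError(f"node {i!r} has an empty network label")
        network_of[i] = net.strip()
    return NodePartition(node_ids=tuple(ids), network_of=network_of, excluded=excluded)


def default_partition() -> NodePartition:
    """The bundled 268-node fixture: 49 cerebellar nodes excluded, 9 cerebral
    networks over the remaining 219 nodes."""
    with resources.files("dynrecon.data").joinpath("partition_268.csv").open() as fh:
        df = pd.read_csv(fh)
    return from_frame(df)


#: canonical 9-network label set used by the demo/synthetic partitions
NETWORK_LABELS = (
    "DMN", "MFN", "FPN", "limbic", "motor",
    "visual_I", "visual_II", "visual_assoc", "BGN",
)


def demo_partition(nodes_per_network: int = 3) -> NodePartition:
    """Small 9-network partition for simulations and tests.

    Every network gets ``nodes_per_network`` nodes; no exclusions.
    """
    if nodes_per_network < 2:
        raise ValueError("nodes_per_network must be >= 2")
    ids, network_of = [], {}
    k = 1
    for net in NETWORK_LABELS:
        for _ in range(nodes_per_network):
            nid = f"n{k:03d}"
            ids.append(nid)
            network_of[nid] = net
            k += 1
    return NodePartition(node_ids=tuple(ids), network_of=network_of)
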