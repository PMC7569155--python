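"""Centrality computation and the triple-median key-node screen.

Three topological features rank each node of the merged network:

* **degree** — the raw number of links incident to the node;
* **betweenness** — the fraction of shortest paths between node pairs
  that pass through the node, normalised by ``(n-1)(n-2)/2`` for an
  undirected ``n``-node graph so values lie in [0, 1];
* **closeness** — the inverse of the farness, i.e. ``(m-1) / sum of
  shortest-path distances`` to the ``m-1`` other nodes of the node's
  connected component (isolated nodes score 0). An optional
  whole-graph scaling by ``(m-1)/(n-1)`` is available for analyzers
  that use it; it is off by default.

A node is a *key node* when all three of its values strictly exceed
the corresponding medians taken over every node of the analysed
network — herb and compound nodes included, since they compete in the
same screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import TARGET_CATEGORIES

CENTRALITY_COLUMNS = ("degree", "betweenness", "closeness")


def degree_centrality(net: nx.Graph) -> dict[str, int]:
    """Raw link count per node (not normalised)."""
    return {n: int(d) for n, d in net.degree()}


def betweenness_centrality(net: nx.Graph) -> dict[str, float]:
    """Pair-normalised shortest-path betweenness in [0, 1].

    Computed with Brandes accumulation; for graphs with fewer than
    three nodes every value is 0 (no intermediate pairs exist).
    """
    n = net.number_of_nodes()
    if n < 3:
        return {node: 0.0 for node in net}
    return nx.betweenness_centrality(net, normalized=True)


def closeness_centrality(net: nx.Graph, whole_graph_scaled: bool = False) -> dict[str, float]:
    """Component-wise closeness ``(m-1)/sum(d)``; 0 for isolated nodes.

    With ``whole_graph_scaled`` the value is additionally multiplied by
    ``(m-1)/(n-1)``, penalising small components.
    """
    return nx.closeness_centrality(net, wf_improved=whole_graph_scaled)


def centrality_table(net: nx.Graph, whole_graph_scaled_closeness: bool = False) -> pd.DataFrame:
    """Per-node degree/betweenness/closeness plus medians and key flags.

    Returns a DataFrame indexed by node id with columns ``category``,
    ``degree``, ``betweenness``, ``closeness`` and ``is_key``; the three
    medians are stored in ``df.attrs["medians"]``. ``is_key`` is true
    iff all three node values strictly exceed their medians.
    """
    deg = degree_centrality(net)
    btw = betweenness_centrality(net)
    clo = closeness_centrality(net, whole_graph_scaled=whole_graph_scaled_closeness)
    nodes = list(net.nodes)
    df = pd.DataFrame(
        {
            "category": [net.nodes[n].get("category", "") for n in nodes],
            "degree": [deg[n] for n in nodes],
            "betweenness": [btw[n] for n in nodes],
            "closeness": [clo[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node_id"),
    )
    medians = {c: float(np.median(df[c].to_numpy())) for c in CENTRALITY_COLUMNS}
    df["is_key"] = (
        (df["degree"] > medians["degree"])
        & (df["betweenness"] > medians["betweenness"])
        & (df["closeness"] > medians["closeness"])
    )
    df.attrs["medians"] = medians
    return df


@dataclass
class KeyNodeSet:
    """Result of the triple-median screen."""

    node_ids: list[str]
    categories: dict[str, str]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            counts: dict[str, int] = {}
            for n in self.node_ids:
                counts[self.categories[n]] = counts.get(self.categories[n], 0) + 1
            self.counts = counts

    def __len__(self) -> int:
        return len(self.node_ids)

    @property
    def gene_target_ids(self) -> list[str]:
        """Key nodes that are gene targets (putative, disease or shared)."""
        return [n for n in self.node_ids if self.categories[n] in TARGET_CATEGORIES]


def screen_key_nodes(table: pd.DataFrame) -> KeyNodeSet:
    """Nodes whose degree, betweenness and closeness all strictly exceed
    the table-level medians.

    With constant centralities nothing exceeds its own median and the
    screen returns the empty set.
    """
    key = table.index[table["is_key"]].tolist()
    cats = table["category"].to_dict()
    return KeyNodeSet(node_ids=key, categories={n: cats[n] for n in key})
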