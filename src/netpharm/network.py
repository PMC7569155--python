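"""Interaction-network construction.

Two graphs are built here. The compound-target network links one herb
node to each retained chemical constituent and each constituent to its
putative gene targets. The merged herb-disease network adds the known
therapeutic targets of the disease and the protein-protein interaction
(PPI) edges among all target genes, after the PPI table has been
screened by its own median combined score.

Graphs are undirected and unweighted for topology purposes; the PPI
combined score is carried as an edge attribute only. Genes appearing
in both the putative and the disease lists collapse into a single node
with category ``shared_target``; target nodes left without any
incident edge after the median screen are dropped by default (herb and
compound nodes are always connected by construction and never drop).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .io import CompoundRecord, DiseaseTarget, PPIEdge, TargetAssociation

logger = logging.getLogger(__name__)

NODE_CATEGORIES = (
    "herb",
    "compound",
    "putative_target",
    "disease_target",
    "shared_target",
)
TARGET_CATEGORIES = ("putative_target", "disease_target", "shared_target")


@dataclass(frozen=True)
class MedianFilterReport:
    """Bookkeeping for the PPI combined-score median screen."""

    median_score: float
    n_edges_in: int
    n_edges_kept: int

    def __post_init__(self) -> None:
        if self.n_edges_kept > self.n_edges_in:
            raise ValueError("kept more edges than were supplied")

    def to_dict(self) -> dict:
        return {
            "median_score": self.median_score,
            "n_edges_in": self.n_edges_in,
            "n_edges_kept": self.n_edges_kept,
        }


def build_compound_target_network(
    herb_id: str,
    compounds: Sequence[CompoundRecord],
    associations: Iterable[TargetAssociation],
) -> nx.Graph:
    """Build the herb / compound / putative-target graph.

    The herb connects to every compound (``herb_compound`` edges) and
    each deduplicated (compound, target) pair contributes one
    ``compound_target`` edge, so the node count is
    ``1 + n_compounds + n_unique_targets`` and the edge count is
    ``n_compounds + n_unique_pairs``. Associations naming a compound
    that is not in ``compounds`` (e.g. filtered out) are skipped with a
    warning and counted in the graph attribute ``n_skipped_associations``.
    """
    g = nx.Graph(name="compound_target", herb_id=herb_id)
    g.add_node(herb_id, category="herb")
    known = set()
    for c in compounds:
        known.add(c.compound_id)
        g.add_node(c.compound_id, category="compound", tanimoto=c.tanimoto)
        g.add_edge(herb_id, c.compound_id, etype="herb_compound")
    n_skipped = 0
    for assoc in associations:
        if assoc.compound_id not in known:
            n_skipped += 1
            continue
        if assoc.gene_symbol not in g:
            g.add_node(assoc.gene_symbol, category="putative_target")
        g.add_edge(assoc.compound_id, assoc.gene_symbol, etype="compound_target")
    if n_skipped:
        logger.warning(
            "skipped %d association(s) referencing unknown compounds", n_skipped
        )
    g.graph["n_skipped_associations"] = n_skipped
    return g


def filter_ppi_by_median(
    edges: Sequence[PPIEdge],
) -> tuple[list[PPIEdge], MedianFilterReport]:
    """Keep PPI edges whose score strictly exceeds the input median.

    The median of an even-length score list is the mean of the two
    middle order statistics, so with all-distinct scores exactly half
    of an even-sized table survives. A degenerate table in which every
    score equals the median keeps nothing: the comparison is strict.
    """
    if len(edges) == 0:
        raise ValueError("cannot median-filter an empty PPI edge list")
    scores = np.array([e.combined_score for e in edges], dtype=float)
    med = float(np.median(scores))
    kept = [e for e in edges if e.combined_score > med]
    report = MedianFilterReport(
        median_score=med, n_edges_in=len(edges), n_edges_kept=len(kept)
    )
    logger.info(
        "median filter: kept %d/%d edges above combined score %.4g",
        report.n_edges_kept,
        report.n_edges_in,
        med,
    )
    return kept, report


def build_merged_network(
    ct_net: nx.Graph,
    disease_targets: Iterable[DiseaseTarget],
    ppi_edges: Sequence[PPIEdge],
    drop_isolated: bool = True,
) -> nx.Graph:
    """Merge the compound-target graph with disease targets and PPI edges.

    Genes present both as putative targets and in the disease list are
    re-labelled ``shared_target`` (one node, counted toward both lists
    in reports). PPI edges are added among all target-category nodes;
    an edge whose endpoint is not otherwise known still introduces its
    endpoints as target nodes of the appropriate category. With
    ``drop_isolated`` (the default) target nodes that end up with no
    incident edge are removed — mirroring how a viewer imports an
    interaction table, which contains only connected nodes.

    ``ppi_edges`` is expected to be median-filtered already; this
    function performs no score screening of its own.
    """
    g = ct_net.copy()
    putative = {
        n for n, d in g.nodes(data=True) if d.get("category") == "putative_target"
    }
    disease = {t.gene_symbol for t in disease_targets}
    for gene in disease:
        if gene in putative:
            g.nodes[gene]["category"] = "shared_target"
        elif gene not in g:
            g.add_node(gene, category="disease_target")
    target_like = {
        n for n, d in g.nodes(data=True) if d.get("category") in TARGET_CATEGORIES
    }
    for e in ppi_edges:
        for endpoint in (e.gene_a, e.gene_b):
            if endpoint not in g:
                # PPI endpoint outside both lists: treat as a disease-side
                # interactor only if declared; otherwise add as putative-side
                # gene is unjustified, so classify by membership.
                cat = "disease_target" if endpoint in disease else "putative_target"
                g.add_node(endpoint, category=cat)
                target_like.add(endpoint)
        if g.has_edge(e.gene_a, e.gene_b):
            # duplicate pair collapses; keep the max score on conflict
            prev = g.edges[e.gene_a, e.gene_b].get("score")
            if prev is None or e.combined_score > prev:
                g.edges[e.gene_a, e.gene_b]["score"] = e.combined_score
            continue
        g.add_edge(e.gene_a, e.gene_b, etype="ppi", score=e.combined_score)
    if drop_isolated:
        isolated = [
            n
            for n in nx.isolates(g)
            if g.nodes[n].get("category") in TARGET_CATEGORIES
        ]
        g.remove_nodes_from(isolated)
        g.graph["n_isolated_dropped"] = len(isolated)
    g.graph["name"] = "merged"
    return g


def category_counts(net: nx.Graph) -> dict[str, int]:
    """Node counts per category, plus totals."""
    counts: dict[str, int] = {c: 0 for c in NODE_CATEGORIES}
    for _, d in net.nodes(data=True):
        counts[d.get("category", "putative_target")] += 1
    counts["nodes"] = net.number_of_nodes()
    counts["edges"] = net.number_of_edges()
    return counts
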