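"""Tabular ingestion and network interchange.

Readers for the tab-separated export dialects the pipeline consumes
(compound tables with structure-similarity scores, compound-target
association lists, disease therapeutic-target lists, scored PPI edge
tables, pathway/GO annotation tables) and writers/readers for the
network interchange formats (GraphML, SIF, node/edge TSV) that
Cytoscape-class viewers accept.

Header contract (tab-delimited, UTF-8, one header row):

===================  =======================================
file                 required columns
===================  =======================================
compound table       compound_id, tanimoto   (name optional)
association table    compound_id, gene_symbol
disease-target list  gene_symbol             (source optional)
PPI edge table       gene_a, gene_b, combined_score
annotation table     term_id, term_name, gene_symbol
plate table          well, group, od
===================  =======================================

Gene symbols are upper-cased and whitespace-trimmed at ingestion so
that tables from different database dialects merge on one canonical
key. Duplicate rows resolve deterministically: associations and
disease targets keep the first occurrence, conflicting PPI scores keep
the maximum. PPI self-loops are dropped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

NETWORK_FORMATS = ("graphml", "sif", "tsv")


class TableFormatError(ValueError):
    """A required column is missing or a value cannot be parsed."""


@dataclass(frozen=True)
class CompoundRecord:
    """One candidate chemical constituent of the herb.

    ``tanimoto`` is the structure-similarity coefficient in [0, 1]
    between the constituent and known drugs; it is consumed, never
    computed here.
    """

    compound_id: str
    name: str
    tanimoto: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.tanimoto <= 1.0:
            raise ValueError(
                f"tanimoto score {self.tanimoto!r} for {self.compound_id!r} "
                "outside [0, 1]"
            )


@dataclass(frozen=True)
class TargetAssociation:
    """A (compound, putative gene target) link."""

    compound_id: str
    gene_symbol: str


@dataclass(frozen=True)
class DiseaseTarget:
    """A known therapeutic target of the disease (OMIM-style list)."""

    gene_symbol: str
    source: str = "OMIM"


@dataclass(frozen=True)
class PPIEdge:
    """An undirected protein-protein interaction with a confidence score."""

    gene_a: str
    gene_b: str
    combined_score: float

    @property
    def pair(self) -> tuple[str, str]:
        """Canonical unordered endpoint pair."""
        return (self.gene_a, self.gene_b) if self.gene_a <= self.gene_b else (
            self.gene_b,
            self.gene_a,
        )


@dataclass
class AnnotationTable:
    """term_id -> (term_name, gene set) mapping for enrichment."""

    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def gene_set(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def term_name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    @property
    def all_genes(self) -> frozenset[str]:
        """Union of annotated genes — the default enrichment background."""
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return frozenset(out)


def _norm_gene(symbol: object) -> str:
    return str(symbol).strip().upper()


def _read_tsv(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound table; malformed rows are reported with line numbers.

    Raises
    ------
    TableFormatError
        If a required column is missing, or any row has an unparsable
        or out-of-range similarity score (all offending data line
        numbers are listed in the message).
    """
    df = _read_tsv(path, required=("compound_id", "tanimoto"))
    records: list[CompoundRecord] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after the header line
        try:
            score = float(row.tanimoto)
        except (TypeError, ValueError):
            bad.append((line_no, f"unparsable tanimoto {row.tanimoto!r}"))
            continue
        name = str(getattr(row, "name_", getattr(row, "name", row.compound_id)))
        try:
            records.append(
                CompoundRecord(
                    compound_id=str(row.compound_id).strip(),
                    name=name.strip(),
                    tanimoto=score,
                )
            )
        except ValueError as exc:
            bad.append((line_no, str(exc)))
    if bad:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad)
        raise TableFormatError(f"{path}: {len(bad)} malformed row(s): {detail}")
    return records


def filter_compounds_by_tanimoto(
    records: Iterable[CompoundRecord], threshold: float = 0.8
) -> list[CompoundRecord]:
    """Keep compounds with similarity strictly greater than ``threshold``.

    The comparison is strict (> threshold), matching the screening
    criterion the score is used for; input order is preserved.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold!r} outside [0, 1]")
    return [r for r in records if r.tanimoto > threshold]


def read_target_table(path: str | Path) -> list[TargetAssociation]:
    """Read compound→target associations, deduplicated on (compound, gene)."""
    df = _read_tsv(path, required=("compound_id", "gene_symbol"))
    seen: set[tuple[str, str]] = set()
    out: list[TargetAssociation] = []
    n_dup = 0
    for row in df.itertuples(index=False):
        gene = _norm_gene(row.gene_symbol)
        if not gene:
            raise TableFormatError(f"{path}: empty gene_symbol")
        key = (str(row.compound_id).strip(), gene)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        out.append(TargetAssociation(*key))
    if n_dup:
        logger.warning("%s: dropped %d duplicate association row(s)", path, n_dup)
    return out


def read_disease_targets(path: str | Path) -> list[DiseaseTarget]:
    """Read a disease therapeutic-target list; first occurrence wins."""
    df = _read_tsv(path, required=("gene_symbol",))
    seen: set[str] = set()
    out: list[DiseaseTarget] = []
    for row in df.itertuples(index=False):
        gene = _norm_gene(row.gene_symbol)
        if not gene or gene in seen:
            continue
        seen.add(gene)
        out.append(DiseaseTarget(gene, str(getattr(row, "source", "OMIM"))))
    return out


def read_ppi_table(path: str | Path) -> list[PPIEdge]:
    """Read a scored PPI edge table.

    Self-loops are dropped (and counted in the log); duplicate
    unordered pairs collapse to one edge keeping the maximum score.
    """
    df = _read_tsv(path, required=("gene_a", "gene_b", "combined_score"))
    best: dict[tuple[str, str], float] = {}
    n_self = 0
    n_dup = 0
    for i, row in enumerate(df.itertuples(index=False)):
        a, b = _norm_gene(row.gene_a), _norm_gene(row.gene_b)
        try:
            score = float(row.combined_score)
        except (TypeError, ValueError):
            raise TableFormatError(
                f"{path}: line {i + 2}: unparsable combined_score "
                f"{row.combined_score!r}"
            ) from None
        if score < 0:
            raise TableFormatError(f"{path}: line {i + 2}: negative score {score}")
        if a == b:
            n_self += 1
            continue
        pair = (a, b) if a <= b else (b, a)
        if pair in best:
            n_dup += 1
            best[pair] = max(best[pair], score)
        else:
            best[pair] = score
    if n_self:
        logger.warning("%s: dropped %d self-loop edge(s)", path, n_self)
    if n_dup:
        logger.warning(
            "%s: collapsed %d duplicate pair(s), keeping max score", path, n_dup
        )
    return [PPIEdge(a, b, s) for (a, b), s in best.items()]


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a long-format (term_id, term_name, gene_symbol) annotation table."""
    df = _read_tsv(path, required=("term_id", "term_name", "gene_symbol"))
    names: dict[str, str] = {}
    genes: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        tid = str(row.term_id).strip()
        names.setdefault(tid, str(row.term_name).strip())
        genes.setdefault(tid, set()).add(_norm_gene(row.gene_symbol))
    table = AnnotationTable(
        {tid: (names[tid], frozenset(gs)) for tid, gs in genes.items() if gs}
    )
    return table


def read_annotations_gmt(path: str | Path) -> AnnotationTable:
    """Read GMT-style annotations (term_id <tab> term_name <tab> gene...)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise TableFormatError(f"{path}: GMT line with <3 fields: {line!r}")
        tid, name, *genes = parts
        terms[tid] = (name, frozenset(_norm_gene(g) for g in genes if g.strip()))
    return AnnotationTable(terms)


# ---------------------------------------------------------------------------
# network interchange


def write_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> list[Path]:
    """Write an interaction network for downstream viewers.

    ``graphml`` carries the node ``category`` and edge ``etype``/``score``
    attributes; ``sif`` uses the edge type as the relation; ``tsv``
    emits a node table and an edge table (``<stem>.nodes.tsv`` /
    ``<stem>.edges.tsv``). Returns the paths written.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
        return [path]
    if format == "sif":
        with open(path, "w") as fh:
            for u, v, data in net.edges(data=True):
                fh.write(f"{u}\t{data.get('etype', 'interacts')}\t{v}\n")
            for node in nx.isolates(net):
                fh.write(f"{node}\n")
        return [path]
    if format == "tsv":
        stem = path.with_suffix("") if path.suffix == ".tsv" else path
        nodes_path = Path(f"{stem}.nodes.tsv")
        edges_path = Path(f"{stem}.edges.tsv")
        nodes = pd.DataFrame(
            [
                {"node_id": n, "category": d.get("category", "")}
                for n, d in sorted(net.nodes(data=True))
            ]
        )
        nodes.to_csv(nodes_path, sep="\t", index=False)
        rows = []
        for u, v, d in net.edges(data=True):
            a, b = sorted((u, v))
            rows.append(
                {
                    "node_a": a,
                    "node_b": b,
                    "etype": d.get("etype", ""),
                    "score": d.get("score", ""),
                }
            )
        pd.DataFrame(sorted(rows, key=lambda r: (r["node_a"], r["node_b"]))).to_csv(
            edges_path, sep="\t", index=False
        ) if rows else pd.DataFrame(
            columns=["node_a", "node_b", "etype", "score"]
        ).to_csv(edges_path, sep="\t", index=False)
        return [nodes_path, edges_path]
    raise ValueError(f"unknown network format {format!r}; expected {NETWORK_FORMATS}")


def read_network(path: str | Path) -> nx.Graph:
    """Read a GraphML network written by :func:`write_network`."""
    g = nx.read_graphml(Path(path))
    return nx.Graph(g)
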