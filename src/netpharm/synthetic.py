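"""Seeded generators emulating every pipeline input.

No compound, target or interaction export is redistributable, so all
stages of the pipeline are exercised on synthetic tables whose
statistical structure mirrors the real database exports: a compound
table with structure-similarity scores straddling the 0.8 screen, a
compound-target association list, a disease therapeutic-target list
overlapping the putative targets, a scored PPI edge table with a
heavy-tailed degree distribution and optional planted hub nodes, an
annotation table with one term optionally enriched in a designated
query, and a replicate OD plate with known group effects.

Every generator takes a :class:`SyntheticScenario` whose ``seed``
fully determines the output (integer-state PRNG, byte-identical files
across runs). Gene symbols are synthetic (``G000001``...) — nothing
generated here carries biological meaning; planted ground truth is
returned alongside each table so recovery tests can score themselves.

:func:`gen_study_scale_tables` produces one deterministic set of
tables sized to the TBM-HCC case study (10 retained compounds, 155
putative targets linked once each, 282 disease targets, a PPI table
whose median screen keeps exactly half), arranged so the merged
network reproduces the study's bookkeeping: 166 nodes / 165 edges for
the compound-target graph and 307 nodes / 1086 edges after merging.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

HERB_ID = "HERB"


def _gene(i: int) -> str:
    return f"G{i:06d}"


def _compound(i: int) -> str:
    return f"CPD{i:04d}"


@dataclass
class SyntheticScenario:
    """Parameter bundle for all generators; ``seed`` fixes every draw.

    The defaults describe a mid-sized benchmark: 25 candidate
    compounds of which 10 pass the 0.8 similarity screen, 155 putative
    and 282 disease targets with 10% overlap, a 200-node
    preferential-attachment PPI layer with 5 planted hubs, 50
    annotation terms with a 4-fold planted enrichment, and a
    four-group MTT plate whose group means equal the case study's
    printed values with noise at the printed SD scale (~0.015 OD).
    """

    seed: int = 0
    # compounds / associations
    n_compounds: int = 25
    n_passing_compounds: int = 10
    tanimoto_threshold: float = 0.8
    n_putative_targets: int = 155
    target_multiplicity: int = 1  # compounds linked per target
    # disease list
    n_disease_targets: int = 282
    overlap_fraction: float = 0.10
    # PPI layer
    ppi_model: str = "preferential_attachment"  # or "erdos_renyi"
    ppi_n_nodes: int = 200
    ppi_param: float = 3  # BA attachment m, or ER edge probability
    score_range: tuple[float, float] = (150.0, 999.0)
    n_planted_hubs: int = 0
    hub_attach_fraction: float = 0.35
    # annotations
    n_terms: int = 50
    term_size_range: tuple[int, int] = (50, 100)
    annotation_background: int = 1000
    query_size: int = 62
    planted_term_enrichment_factor: float = 4.0
    # plate
    plate_group_means: dict[str, float] = field(
        default_factory=lambda: {
            "control": 0.5891,
            "tbm_serum_25pct": 0.4550,
            "tbm_serum_12.5pct": 0.5278,
            "tbm_serum_6.25pct": 0.5596,
        }
    )
    plate_noise_sd: float = 0.015
    plate_replicates: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        for name in (
            "n_compounds",
            "n_passing_compounds",
            "n_putative_targets",
            "n_disease_targets",
            "n_planted_hubs",
            "n_terms",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_passing_compounds > self.n_compounds:
            raise ValueError("n_passing_compounds exceeds n_compounds")
        if self.ppi_model not in ("preferential_attachment", "erdos_renyi"):
            raise ValueError(f"unknown ppi_model {self.ppi_model!r}")


def _stream_rng(scenario: SyntheticScenario, stream: int) -> np.random.Generator:
    """Independent deterministic generator for one output stream."""
    return np.random.default_rng([scenario.seed, stream])


def gen_compound_table(
    scenario: SyntheticScenario,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Compound and association tables with a known passing subset.

    Exactly ``n_passing_compounds`` similarity scores land strictly
    above the screen threshold; associations link each putative target
    to ``target_multiplicity`` distinct passing compounds (round-robin
    with a random offset, so multiplicity is exact).
    """
    rng = _stream_rng(scenario, 1)
    thr = scenario.tanimoto_threshold
    n, n_pass = scenario.n_compounds, scenario.n_passing_compounds
    scores = np.concatenate(
        [
            rng.uniform(min(thr + 0.01, 1.0), 1.0, size=n_pass),
            rng.uniform(0.0, max(thr - 0.01, 0.0), size=n - n_pass),
        ]
    )
    order = rng.permutation(n)
    ids = [_compound(i + 1) for i in range(n)]
    compounds = pd.DataFrame(
        {
            "compound_id": ids,
            "name": [f"constituent-{i + 1}" for i in range(n)],
            "tanimoto": np.round(scores[order], 4),
        }
    )
    passing = compounds.loc[compounds["tanimoto"] > thr, "compound_id"].tolist()
    rows = []
    if passing and scenario.n_putative_targets and scenario.target_multiplicity:
        mult = min(scenario.target_multiplicity, len(passing))
        offsets = rng.integers(0, len(passing), size=scenario.n_putative_targets)
        for t in range(scenario.n_putative_targets):
            gene = _gene(t + 1)
            for j in range(mult):
                rows.append(
                    {
                        "compound_id": passing[(offsets[t] + j) % len(passing)],
                        "gene_symbol": gene,
                    }
                )
    associations = pd.DataFrame(rows, columns=["compound_id", "gene_symbol"])
    truth = {
        "passing_compounds": passing,
        "n_passing": len(passing),
        "putative_targets": [
            _gene(t + 1) for t in range(scenario.n_putative_targets)
        ],
    }
    return compounds, associations, truth


def gen_disease_targets(
    scenario: SyntheticScenario,
) -> tuple[pd.DataFrame, dict]:
    """Disease-target list overlapping the putative targets.

    ``overlap_fraction`` of the disease list reuses putative-target
    symbols (the shared genes); the rest are fresh symbols numbered
    after the putative block.
    """
    rng = _stream_rng(scenario, 2)
    n_overlap = int(round(scenario.overlap_fraction * scenario.n_disease_targets))
    n_overlap = min(n_overlap, scenario.n_putative_targets)
    shared = sorted(
        rng.choice(scenario.n_putative_targets, size=n_overlap, replace=False) + 1
    )
    genes = [_gene(i) for i in shared] + [
        _gene(scenario.n_putative_targets + i + 1)
        for i in range(scenario.n_disease_targets - n_overlap)
    ]
    df = pd.DataFrame({"gene_symbol": genes, "source": "OMIM"})
    return df, {"shared_genes": [_gene(i) for i in shared]}


def gen_ppi_network(scenario: SyntheticScenario) -> tuple[pd.DataFrame, dict]:
    """Scored PPI edge table with optional planted hub nodes.

    The base layer is preferential-attachment (heavy-tailed degrees,
    matching the 6-61 degree span seen on real interaction exports of
    this size) or Erdős–Rényi. Planted hubs attach to
    ``hub_attach_fraction`` of the base nodes and to each other, so
    they dominate degree, betweenness and closeness by construction.
    Combined scores are i.i.d. uniform over ``score_range``, so close
    to half of any large table falls below its own median.
    """
    rng = _stream_rng(scenario, 3)
    n = scenario.ppi_n_nodes
    if scenario.ppi_model == "preferential_attachment":
        m = max(1, int(scenario.ppi_param))
        base = (
            nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
            if n > m
            else nx.empty_graph(n)
        )
    else:
        base = nx.fast_gnp_random_graph(
            n, float(scenario.ppi_param), seed=int(rng.integers(2**31))
        )
    g = nx.relabel_nodes(base, {i: _gene(i + 1) for i in range(n)})
    hubs = [f"HUB{h + 1:03d}" for h in range(scenario.n_planted_hubs)]
    n_attach = max(1, int(round(scenario.hub_attach_fraction * n))) if n else 0
    for h in hubs:
        targets = rng.choice(n, size=min(n_attach, n), replace=False)
        for t in targets:
            g.add_edge(h, _gene(t + 1))
        for other in hubs:
            if other != h:
                g.add_edge(h, other)
    lo, hi = scenario.score_range
    edges = sorted(tuple(sorted(e)) for e in g.edges)
    scores = np.round(rng.uniform(lo, hi, size=len(edges)), 3)
    df = pd.DataFrame(
        {
            "gene_a": [a for a, _ in edges],
            "gene_b": [b for _, b in edges],
            "combined_score": scores,
        }
    )
    return df, {"hubs": hubs, "n_edges": len(edges)}


def gen_annotations(scenario: SyntheticScenario) -> tuple[pd.DataFrame, dict]:
    """Annotation table plus a designated query with one planted term.

    The background is ``annotation_background`` synthetic genes; the
    query is a uniform draw of ``query_size`` of them. A term of
    nominal size ``K`` includes each gene independently: query genes
    with probability ``factor * K / N`` (capped at 1) and non-query
    genes with the probability that keeps the expected term size at
    ``K``. The factor is therefore the fold over-representation of
    query genes in the term — ``TERM0001`` carries
    ``planted_term_enrichment_factor``, every other term factor 1, so
    a factor of 1 plants nothing.
    """
    rng = _stream_rng(scenario, 4)
    N = scenario.annotation_background
    background = [_gene(i + 1) for i in range(N)]
    nq = min(scenario.query_size, N)
    query = sorted(rng.choice(N, size=nq, replace=False))
    query_genes = [_gene(i + 1) for i in query]
    in_query = np.zeros(N, dtype=bool)
    in_query[query] = True
    lo, hi = scenario.term_size_range
    rows = []
    for t in range(scenario.n_terms):
        size = int(rng.integers(lo, hi + 1))
        factor = scenario.planted_term_enrichment_factor if t == 0 else 1.0
        p_query = min(1.0, factor * size / N)
        p_other = max(0.0, (size - nq * p_query) / (N - nq)) if N > nq else 0.0
        include = np.where(in_query, rng.random(N) < p_query, rng.random(N) < p_other)
        tid = f"TERM{t + 1:04d}"
        for gi in np.flatnonzero(include):
            rows.append(
                {
                    "term_id": tid,
                    "term_name": f"synthetic process {t + 1}",
                    "gene_symbol": _gene(gi + 1),
                }
            )
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "gene_symbol"])
    truth = {
        "planted_term": "TERM0001" if scenario.n_terms else None,
        "query_genes": query_genes,
        "background": background,
    }
    return df, truth


def gen_plate(scenario: SyntheticScenario) -> tuple[pd.DataFrame, dict]:
    """Replicate OD plate: group mean × (1 + Gaussian noise), floored at 0.

    ``plate_noise_sd`` is the *relative* noise SD, sized so that with
    the default ~0.5 OD means the absolute spread matches the ~0.01
    OD replicate SDs plate readers of this kind report. The true
    inhibition ratios implied by the noiseless means are returned as
    ground truth.
    """
    rng = _stream_rng(scenario, 5)
    means = scenario.plate_group_means
    rows = []
    for group, mu in means.items():
        noise = rng.normal(0.0, scenario.plate_noise_sd, size=scenario.plate_replicates)
        ods = np.maximum(mu * (1.0 + noise), 0.0)
        for i, od in enumerate(ods):
            rows.append({"well": f"{group}_{i + 1}", "group": group, "od": round(float(od), 4)})
    df = pd.DataFrame(rows, columns=["well", "group", "od"])
    ctrl = means.get("control")
    true_ir = {
        g: (ctrl - mu) / ctrl * 100.0
        for g, mu in means.items()
        if ctrl and g != "control"
    }
    return df, {"true_inhibition_ratio_pct": true_ir}


# ---------------------------------------------------------------------------
# study-scale emulation


def gen_study_scale_tables(seed: int = 0) -> tuple[dict[str, pd.DataFrame], dict]:
    """Deterministic tables sized to the TBM-HCC case study.

    Dimensions are fixed to the published bookkeeping: 10 of 25
    candidate compounds pass the 0.8 similarity screen; 155 putative
    targets each link to exactly one passing compound (166 nodes, 165
    edges); 282 disease targets of which 30 coincide with putative
    targets; and a 1842-row PPI table whose scores split cleanly at
    the median so exactly 921 edges survive. The surviving edges span
    the 155 putative targets and 141 of the 252 disease-only genes
    (heavy-tailed preferential-attachment topology); the other 111
    disease-only genes appear only in below-median rows and drop as
    isolated nodes, which yields a merged network of
    1 + 10 + 155 + 141 = 307 nodes and 165 + 921 = 1086 edges.

    Returns ``(tables, ground_truth)`` where ``tables`` maps
    ``compounds`` / ``targets`` / ``disease`` / ``ppi`` to DataFrames
    in the ingestion dialects.
    """
    scenario = SyntheticScenario(
        seed=seed,
        n_compounds=25,
        n_passing_compounds=10,
        n_putative_targets=155,
        target_multiplicity=1,
        n_disease_targets=282,
    )
    compounds, associations, ct_truth = gen_compound_table(scenario)

    rng = _stream_rng(scenario, 6)
    n_put, n_disease, n_shared = 155, 282, 30
    n_connected_disease_only, n_isolated = 141, 111
    shared_idx = sorted(rng.choice(n_put, size=n_shared, replace=False) + 1)
    shared = [_gene(i) for i in shared_idx]
    disease_only = [_gene(n_put + i + 1) for i in range(n_disease - n_shared)]
    disease = pd.DataFrame(
        {"gene_symbol": shared + disease_only, "source": "OMIM"}
    )
    putative = [_gene(i + 1) for i in range(n_put)]
    connected_disease = disease_only[:n_connected_disease_only]
    isolated_disease = disease_only[n_connected_disease_only:]
    assert len(isolated_disease) == n_isolated

    # kept layer: preferential-attachment graph on the 296 genes that
    # must stay connected, padded with random extra edges to 921
    kept_nodes = putative + connected_disease
    n_kept_nodes, n_kept_edges = len(kept_nodes), 921
    base = nx.barabasi_albert_graph(n_kept_nodes, 3, seed=int(rng.integers(2**31)))
    perm = rng.permutation(n_kept_nodes)
    g = nx.relabel_nodes(base, {i: kept_nodes[perm[i]] for i in range(n_kept_nodes)})
    while g.number_of_edges() < n_kept_edges:
        a, b = rng.choice(n_kept_nodes, size=2, replace=False)
        g.add_edge(kept_nodes[a], kept_nodes[b])
    kept_pairs = sorted(tuple(sorted(e)) for e in g.edges)

    # discarded layer: below-median rows over all genes; every
    # to-be-isolated disease gene appears here (and only here)
    all_genes = putative + disease_only
    taken = set(kept_pairs)
    discard_pairs: list[tuple[str, str]] = []
    for gene in isolated_disease:
        while True:
            other = all_genes[int(rng.integers(len(all_genes)))]
            pair = tuple(sorted((gene, other)))
            if other != gene and pair not in taken:
                taken.add(pair)
                discard_pairs.append(pair)
                break
    while len(discard_pairs) < n_kept_edges:
        a, b = rng.choice(len(all_genes), size=2, replace=False)
        pair = tuple(sorted((all_genes[a], all_genes[b])))
        if pair not in taken:
            taken.add(pair)
            discard_pairs.append(pair)

    kept_scores = np.round(rng.uniform(701.0, 999.0, size=len(kept_pairs)), 3)
    discard_scores = np.round(rng.uniform(150.0, 699.0, size=len(discard_pairs)), 3)
    ppi = pd.DataFrame(
        {
            "gene_a": [a for a, _ in kept_pairs] + [a for a, _ in discard_pairs],
            "gene_b": [b for _, b in kept_pairs] + [b for _, b in discard_pairs],
            "combined_score": np.concatenate([kept_scores, discard_scores]),
        }
    ).sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)

    tables = {
        "compounds": compounds,
        "targets": associations,
        "disease": disease,
        "ppi": ppi,
    }
    truth = {
        "herb_id": HERB_ID,
        "n_passing_compounds": len(ct_truth["passing_compounds"]),
        "n_putative_targets": n_put,
        "n_disease_targets": n_disease,
        "n_shared": n_shared,
        "compound_target_nodes": 1 + 10 + n_put,
        "compound_target_edges": 10 + n_put,
        "ppi_edges_in": 2 * n_kept_edges,
        "ppi_edges_kept": n_kept_edges,
        "merged_nodes": 1 + 10 + n_put + n_connected_disease_only,
        "merged_edges": 10 + n_put + n_kept_edges,
        "n_isolated_dropped": n_isolated,
    }
    return tables, truth


# ---------------------------------------------------------------------------
# file emission


def write_scenario(scenario: SyntheticScenario, outdir: str | Path) -> dict[str, Path]:
    """Emit every synthetic table as TSV plus ``ground_truth.json``.

    File names and dialects match what the ingestion readers expect:
    ``compounds.tsv``, ``targets.tsv``, ``disease_targets.tsv``,
    ``ppi.tsv``, ``annotations.tsv``, ``plate.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    compounds, associations, ct_truth = gen_compound_table(scenario)
    disease, d_truth = gen_disease_targets(scenario)
    ppi, ppi_truth = gen_ppi_network(scenario)
    ann, ann_truth = gen_annotations(scenario)
    plate, plate_truth = gen_plate(scenario)
    frames = {
        "compounds.tsv": compounds,
        "targets.tsv": associations,
        "disease_targets.tsv": disease,
        "ppi.tsv": ppi,
        "annotations.tsv": ann,
        "plate.tsv": plate,
    }
    paths: dict[str, Path] = {}
    for name, df in frames.items():
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path
    truth = {
        "scenario": asdict(scenario),
        "compounds": ct_truth,
        "disease": d_truth,
        "ppi": ppi_truth,
        "annotations": {k: v for k, v in ann_truth.items() if k != "background"},
        "plate": plate_truth,
    }
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    paths["ground_truth.json"] = truth_path
    return paths
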