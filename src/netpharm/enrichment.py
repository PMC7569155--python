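"""Local over-representation analysis of gene sets.

Replaces a web enrichment service with an in-process test. For a
query of ``n`` genes drawn from a background of ``N`` annotated genes,
a term annotating ``K`` background genes and overlapping the query in
``k`` genes is scored with the hypergeometric upper tail

    p = P(X >= k),   X ~ Hypergeometric(N, K, n)

computed in log-space via the survival function for numerical
stability. The conservative EASE variant — the same tail with the
observed overlap decremented by one (floored at zero) — is offered
because popular annotation servers apply it. Multiple-testing control
uses Benjamini-Hochberg step-up adjustment.

The background defaults to the union of all annotated genes in the
annotation table; query genes outside the background are dropped with
a logged count. Terms that do not overlap the query are omitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotationTable

logger = logging.getLogger(__name__)

METHODS = ("hypergeometric", "ease")
CORRECTIONS = ("none", "benjamini_hochberg")


@dataclass(frozen=True)
class EnrichmentResult:
    """One annotation term with its overlap and significance."""

    term_id: str
    term_name: str
    k: int  # overlap count
    K: int  # term size in background
    n: int  # query size in background
    N: int  # background size
    p_raw: float
    p_adj: float
    overlap_genes: tuple[str, ...]


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability ``P(X >= k)`` for X ~ Hypergeometric(N, K, n).

    ``N`` is the background size, ``K`` the number of annotated
    successes in it, ``n`` the number drawn (query size), ``k`` the
    observed overlap. ``k = 0`` gives exactly 1.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(K, n, N) < 0:
        raise ValueError(
            f"invalid hypergeometric parameters k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates the tail stably in log space
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ease_tail(k: int, K: int, n: int, N: int) -> float:
    """EASE score: hypergeometric tail at ``max(k-1, 0)``.

    Always at least as large as the plain tail for the same counts.
    """
    return hypergeometric_tail(max(k - 1, 0), K, n, N)


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Step-up false-discovery-rate adjustment, each value capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def enrich_gene_set(
    query: Iterable[str],
    annotations: AnnotationTable,
    background: Iterable[str] | None = None,
    method: str = "hypergeometric",
    correction: str = "benjamini_hochberg",
) -> list[EnrichmentResult]:
    """Score every annotation term against a query gene set.

    Results carry one entry per term with at least one overlapping
    gene, sorted ascending by raw p-value with term id as tiebreak.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if correction not in CORRECTIONS:
        raise ValueError(
            f"unknown correction {correction!r}; expected one of {CORRECTIONS}"
        )
    bg = frozenset(background) if background is not None else annotations.all_genes
    if not bg:
        raise ValueError("empty enrichment background")
    query_set = frozenset(query)
    dropped = len(query_set - bg)
    if dropped:
        logger.info("dropped %d query gene(s) outside the background", dropped)
    query_set &= bg
    n, N = len(query_set), len(bg)
    tail = hypergeometric_tail if method == "hypergeometric" else ease_tail

    rows: list[tuple[str, str, int, int, tuple[str, ...], float]] = []
    for term_id in sorted(annotations.terms):
        term_name, genes = annotations.terms[term_id]
        term_bg = genes & bg
        overlap = tuple(sorted(term_bg & query_set))
        k, K = len(overlap), len(term_bg)
        if k == 0 or K == 0:
            continue
        rows.append((term_id, term_name, k, K, overlap, tail(k, K, n, N)))
    if not rows:
        return []
    p_raw = [r[5] for r in rows]
    p_adj = benjamini_hochberg(p_raw) if correction == "benjamini_hochberg" else p_raw
    results = [
        EnrichmentResult(
            term_id=tid,
            term_name=tname,
            k=k,
            K=K,
            n=n,
            N=N,
            p_raw=p,
            p_adj=q,
            overlap_genes=overlap,
        )
        for (tid, tname, k, K, overlap, p), q in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results
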