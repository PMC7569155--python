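"""Reference summaries bundled for worked examples and offline validation.

The package re-implements an integrative serum-pharmacology plus
network-pharmacology analysis of Tu-Bei-Mu (TBM, the bulb of
*Bolbostemma paniculatum*) acting on hepatocellular carcinoma (HCC).
This module bundles the small printed summaries of that case study so
that examples and checks run without any database access:

* microplate OD summaries (mean, SD, n=3) for the HCC cell line
  BEL-7404 and the normal liver line L-02 under graded TBM-serum
  doses, with the inhibition ratios the plates reported;
* the dimensions of the two interaction networks and of the
  key-node screen;
* centrality triples (degree, betweenness, closeness) of four
  representative key targets, and the value ranges spanned by the 62
  key gene targets.

Only summaries are bundled — the underlying compound, target and
interaction exports are not redistributable, which is why the
:mod:`netpharm.synthetic` generators emulate their structure instead.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# MTT plate summaries: group -> (mean OD at 570 nm, SD, n replicates).
# Reported inhibition ratios (%) are carried alongside; the 6.25% dose
# on BEL-7404 and all L-02 ratios deviate slightly from mean-based
# recomputation (see docs/methods.md) and are kept verbatim.

PLATE_BEL7404: dict[str, tuple[float, float, int]] = {
    "control": (0.5891, 0.0061, 3),
    "tbm_serum_25pct": (0.4550, 0.0089, 3),
    "tbm_serum_12.5pct": (0.5278, 0.0162, 3),
    "tbm_serum_6.25pct": (0.5596, 0.0158, 3),
}
REPORTED_IR_BEL7404: dict[str, float] = {
    "tbm_serum_25pct": 22.8,
    "tbm_serum_12.5pct": 10.4,
    "tbm_serum_6.25pct": 5.5,
}

PLATE_L02: dict[str, tuple[float, float, int]] = {
    "control": (0.4891, 0.0055, 3),
    "tbm_serum_25pct": (0.4633, 0.0146, 3),
    "tbm_serum_12.5pct": (0.4775, 0.0127, 3),
    "tbm_serum_6.25pct": (0.4823, 0.0166, 3),
}
REPORTED_IR_L02: dict[str, float] = {
    "tbm_serum_25pct": 5.4,
    "tbm_serum_12.5pct": 2.5,
    "tbm_serum_6.25pct": 1.9,
}

# ---------------------------------------------------------------------------
# Network dimensions of the case study.

COMPOUND_TARGET_COUNTS = {
    "herbs": 1,
    "compounds": 10,
    "putative_targets": 155,
    "nodes": 166,
    "edges": 165,
}
MERGED_NETWORK_COUNTS = {
    "disease_targets_listed": 282,
    "nodes": 307,
    "edges": 1086,
    "key_nodes": 66,
    "key_gene_targets": 62,
    "key_putative_targets": 36,
    "key_disease_targets": 26,
    "key_compounds": 3,
    "key_herbs": 1,
}

# Centrality triples of four representative key targets on the merged
# network: gene -> (degree, normalised betweenness, closeness).
KEY_TARGET_CENTRALITIES: dict[str, tuple[int, float, float]] = {
    "TP53": (61, 0.1278, 0.4129),
    "CASP3": (24, 0.0246, 0.3711),
    "BCL2": (12, 0.0028, 0.3333),
    "BAX": (8, 4.55e-4, 0.3271),
}
# Ranges spanned by the 62 key gene targets.
KEY_TARGET_RANGES = {
    "degree": (6, 61),
    "betweenness": (4.55e-4, 0.1279),
    "closeness": (0.3252, 0.4287),
}

# ---------------------------------------------------------------------------
# Pathway / biological-process memberships of the key targets: term id
# -> (term name, key-target genes annotated to it). Used by the
# synthetic annotation fixture that emulates the case study's
# enrichment stage.

PATHWAY_KEY_TARGETS: dict[str, tuple[str, tuple[str, ...]]] = {
    "GO:0070059": (
        "intrinsic apoptotic signaling pathway in response to endoplasmic "
        "reticulum stress",
        ("BCL2", "BAX", "APAF1"),
    ),
    "GO:0008635": (
        "activation of cysteine-type endopeptidase activity involved in "
        "apoptotic process by cytochrome c",
        ("BAX", "APAF1"),
    ),
    "GO:0043123": (
        "positive regulation of I-kappaB kinase/NF-kappaB signaling",
        ("HMOX1", "CASP8", "ABL1", "CTNNB1"),
    ),
    "GO:0070374": (
        "positive regulation of ERK1 and ERK2 cascade",
        ("EGFR", "ABL1", "TGFB1", "KDR"),
    ),
    "hsa04152": (
        "AMPK signaling pathway",
        ("AKT1", "CREB1", "PPARG", "PRKAB2", "FBP1", "PRKAB1", "FASN",
         "PIK3CA", "ELAVL1", "RPS6KB1", "PRKAA1", "IRS1"),
    ),
    "hsa04068": (
        "FoxO signaling pathway",
        ("EGFR", "AKT1", "PRMT1", "MAPK14", "PRKAB2", "PRKAB1", "PIK3CA",
         "MDM2", "PRKAA1", "IRS1", "TGFB1"),
    ),
    "hsa04115": (
        "p53 signaling pathway",
        ("CASP3", "RRM2", "BAX", "CASP8", "TP53", "MDM2", "RRM2B", "APAF1"),
    ),
    "hsa04151": (
        "PI3K-Akt signaling pathway",
        ("EGFR", "AKT1", "YWHAZ", "BCL2", "CREB1", "TP53", "MDM2", "PIK3CA",
         "RPS6KB1", "PRKAA1", "IRS1", "YWHAE", "KDR"),
    ),
    "hsa04668": (
        "TNF signaling pathway",
        ("AKT1", "CASP3", "PTGS2", "MAPK14", "CREB1", "CASP8", "PIK3CA"),
    ),
    "hsa04920": (
        "Adipocytokine signaling pathway",
        ("AKT1", "ACSL1", "PRKAB2", "PRKAB1", "PRKAA1", "IRS1"),
    ),
    "hsa04370": (
        "VEGF signaling pathway",
        ("AKT1", "PTGS2", "MAPK14", "PIK3CA", "KDR"),
    ),
    "hsa04150": (
        "mTOR signaling pathway",
        ("AKT1", "PIK3CA", "RPS6KB1", "PRKAA1", "IRS1"),
    ),
    "hsa04012": (
        "ErbB signaling pathway",
        ("EGFR", "AKT1", "PIK3CA", "RPS6KB1", "ABL1"),
    ),
    "hsa04015": (
        "Rap1 signaling pathway",
        ("EGFR", "AKT1", "ADCY1", "MAPK14", "PIK3CA", "KDR", "CTNNB1"),
    ),
    "hsa04390": (
        "Hippo signaling pathway",
        ("AFP", "YWHAZ", "YWHAE", "TGFB1", "CTNNB1", "AXIN1"),
    ),
    "hsa04010": (
        "MAPK signaling pathway",
        ("EGFR", "AKT1", "CASP3", "MAPK14", "TP53", "TGFB1", "HSPA8"),
    ),
    "hsa04510": (
        "Focal adhesion",
        ("EGFR", "AKT1", "BCL2", "PIK3CA", "KDR", "CTNNB1"),
    ),
}


def key_target_union() -> frozenset[str]:
    """All key-target genes named across the bundled pathway rows."""
    out: set[str] = set()
    for _, genes in PATHWAY_KEY_TARGETS.values():
        out |= set(genes)
    return frozenset(out)
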