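import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from netpharm.io import AnnotationTable
from netpharm.synthetic import gen_study_scale_tables


@pytest.fixture(scope="session")
def study_tables(tmp_path_factory):
    """Study-scale synthetic tables written to disk, plus ground truth."""
    tables, truth = gen_study_scale_tables(seed=20)
    d = tmp_path_factory.mktemp("study")
    paths = {}
    for name, df in tables.items():
        p = d / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return {"paths": paths, "truth": truth, "tables": tables}


@pytest.fixture
def toy_network():
    """Small typed interaction network: herb-compound-target chain plus PPI."""
    g = nx.Graph()
    g.add_node("HERB", category="herb")
    for c in ("C1", "C2"):
        g.add_node(c, category="compound")
        g.add_edge("HERB", c, etype="herb_compound")
    for c, t in (("C1", "T1"), ("C1", "T2"), ("C2", "T3")):
        g.add_node(t, category="putative_target")
        g.add_edge(c, t, etype="compound_target")
    g.add_edge("T1", "T3", etype="ppi", score=850.0)
    return g


def annotation_table_from_df(df):
    names, genes = {}, {}
    for row in df.itertuples(index=False):
        names.setdefault(row.term_id, row.term_name)
        genes.setdefault(row.term_id, set()).add(row.gene_symbol)
    return AnnotationTable(
        {t: (names[t], frozenset(g)) for t, g in genes.items()}
    )
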