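"""Config-driven orchestration of the full analysis.

One :func:`run_pipeline` call executes ingest → compound filter →
compound-target network → PPI median screen → merged network →
centrality table → key-node screen → enrichment of the key gene
targets → plate statistics (when a plate is supplied), writing every
artifact plus a JSON run report with the stage-by-stage counts.
Re-running with identical config and inputs reproduces identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__, bioassay, enrichment, io, network, topology

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The run configuration is invalid or references missing files."""


@dataclass
class RunConfig:
    """Validated inputs and knobs for one pipeline run."""

    compounds: str
    targets: str
    disease: str
    ppi: str
    out_dir: str
    annotations: str | None = None
    plate: str | None = None
    herb_id: str = "HERB"
    tanimoto_threshold: float = 0.8
    median_filter: bool = True
    drop_isolated: bool = True
    closeness_whole_graph_scaled: bool = False
    enrichment_method: str = "hypergeometric"
    enrichment_correction: str = "benjamini_hochberg"
    od_blank: float = 0.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for attr in ("compounds", "targets", "disease", "ppi", "annotations", "plate"):
            value = getattr(self, attr)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"{attr} file not found: {value}")
        if not 0.0 <= self.tanimoto_threshold <= 1.0:
            raise ConfigError("tanimoto_threshold outside [0, 1]")
        if self.enrichment_method not in enrichment.METHODS:
            raise ConfigError(f"unknown enrichment_method {self.enrichment_method!r}")
        if self.enrichment_correction not in enrichment.CORRECTIONS:
            raise ConfigError(
                f"unknown enrichment_correction {self.enrichment_correction!r}"
            )
        if self.od_blank < 0:
            raise ConfigError("od_blank must be non-negative")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run report (also written to
    ``<out_dir>/report.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "netpharm",
        "version": __version__,
        "started_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "config": asdict(config),
        "counts": {},
        "artifacts": [],
    }
    counts = report["counts"]

    def _emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        report["artifacts"].append(name)

    # ingest + compound screen
    compounds_all = io.read_compound_table(config.compounds)
    compounds = io.filter_compounds_by_tanimoto(
        compounds_all, config.tanimoto_threshold
    )
    counts["compounds_in"] = len(compounds_all)
    counts["compounds_kept"] = len(compounds)
    associations = io.read_target_table(config.targets)
    disease_targets = io.read_disease_targets(config.disease)
    ppi_edges = io.read_ppi_table(config.ppi)
    counts["associations"] = len(associations)
    counts["disease_targets"] = len(disease_targets)
    counts["ppi_edges_in"] = len(ppi_edges)

    # networks
    ct_net = network.build_compound_target_network(
        config.herb_id, compounds, associations
    )
    counts["ct_nodes"] = ct_net.number_of_nodes()
    counts["ct_edges"] = ct_net.number_of_edges()
    _emit("compound_target.graphml", lambda p: io.write_network(ct_net, p, "graphml"))

    if config.median_filter:
        kept_edges, median_report = network.filter_ppi_by_median(ppi_edges)
        report["median_filter"] = median_report.to_dict()
    else:
        kept_edges = list(ppi_edges)
        report["median_filter"] = None
    counts["ppi_edges_kept"] = len(kept_edges)
    merged = network.build_merged_network(
        ct_net, disease_targets, kept_edges, drop_isolated=config.drop_isolated
    )
    counts["merged_nodes"] = merged.number_of_nodes()
    counts["merged_edges"] = merged.number_of_edges()
    counts["merged_by_category"] = network.category_counts(merged)
    _emit("merged.graphml", lambda p: io.write_network(merged, p, "graphml"))
    _emit("merged", lambda p: io.write_network(merged, p, "tsv"))

    # topology + screen
    table = topology.centrality_table(
        merged, whole_graph_scaled_closeness=config.closeness_whole_graph_scaled
    )
    key_set = topology.screen_key_nodes(table)
    counts["key_nodes"] = len(key_set)
    counts["key_nodes_by_category"] = key_set.counts
    counts["key_gene_targets"] = len(key_set.gene_target_ids)
    report["centrality_medians"] = table.attrs["medians"]
    _emit(
        "centrality.tsv",
        lambda p: table.reset_index().to_csv(p, sep="\t", index=False),
    )
    _emit(
        "key_nodes.tsv",
        lambda p: table.loc[key_set.node_ids]
        .reset_index()
        .to_csv(p, sep="\t", index=False),
    )

    # enrichment of the key gene targets
    if config.annotations:
        annotations = io.read_annotations(config.annotations)
        results = enrichment.enrich_gene_set(
            key_set.gene_target_ids,
            annotations,
            method=config.enrichment_method,
            correction=config.enrichment_correction,
        )
        counts["enriched_terms"] = len(results)
        import pandas as pd

        enr_df = pd.DataFrame(
            [
                {
                    "term_id": r.term_id,
                    "term_name": r.term_name,
                    "key_targets": ", ".join(r.overlap_genes),
                    "k": r.k,
                    "K": r.K,
                    "n": r.n,
                    "N": r.N,
                    "p_value": r.p_raw,
                    "p_adj": r.p_adj,
                }
                for r in results
            ]
        )
        _emit("enrichment.tsv", lambda p: enr_df.to_csv(p, sep="\t", index=False))

    # plate statistics
    if config.plate:
        plate = bioassay.read_plate(config.plate, od_blank=config.od_blank)
        summary = bioassay.summarize_plate(plate)
        counts["plate_groups"] = len(plate.groups)
        _emit("plate_summary.tsv", lambda p: summary.to_csv(p, sep="\t", index=False))

    report["finished_utc"] = datetime.now(timezone.utc).isoformat(timespec="seconds")
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    report["artifacts"].append("report.json")
    return report
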