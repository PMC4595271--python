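"""End-to-end orchestration of the analysis stages over a bundle directory.

A bundle directory holds the tabular inputs (see
:class:`terpomics.synthetic.Bundle`); the pipeline quantifies expression
(multi-read rescue + RPKM), calls regional DEGs, scales and clusters
profiles, summarizes metabolites (totals, OAV, ANOVA/Duncan), correlates
genes with metabolites, nominates candidate genes, builds the TF
co-expression and anchored networks, validates qPCR against RPKM and
summarizes the climate table.  Every output file is recorded in a run
manifest with a content hash, so identical inputs and configuration
produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as climate_mod
from . import coexpression, integration, metabolites as metab_mod, profiles, qpcr as qpcr_mod
from .expression import Comparison, assign_multireads, call_degs, rpkm_matrix
from .synthetic import Bundle

log = logging.getLogger("terpomics")

#: read-alignment settings echoed for provenance only (alignment itself is
#: upstream of this package)
ALIGNMENT_PROVENANCE = {"max_mismatches": 2, "max_hits_per_read": 10}

STRUCTURAL_CATEGORIES = ("MEP", "MVA", "TPS-a", "TPS-b", "TPS-g", "UGT")


@dataclass
class PipelineConfig:
    bundle_dir: str = "."
    output_dir: str = "results"
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    r_network: float = 0.8
    network_inclusive: bool = True
    r_trend: float = 0.7
    oav_threshold: float = 1.0
    r2_qpcr: float = 0.7
    kmeans_k: int = 9
    kmeans_seed: int = 1
    correlation_mode: str = "instantaneous"
    log_pseudocount: float = 1.0
    anchors: list[str] = field(default_factory=list)

    def validate(self) -> None:
        checks = [
            (0 < self.alpha <= 1, f"alpha must be in (0, 1], got {self.alpha}"),
            (self.lfc_threshold >= 0, "lfc_threshold must be >= 0"),
            (0 <= self.r_network <= 1, "r_network must be in [0, 1]"),
            (0 <= self.r_trend <= 1, "r_trend must be in [0, 1]"),
            (self.oav_threshold > 0, "oav_threshold must be positive"),
            (0 < self.r2_qpcr < 1, "r2_qpcr must be in (0, 1)"),
            (self.kmeans_k >= 2, "kmeans_k must be >= 2"),
            (
                self.correlation_mode in integration.MODES,
                f"correlation_mode must be one of {integration.MODES}",
            ),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**raw)
        config.validate()
        return config

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _cell_label(region, year, stage) -> str:
    return f"{region}|{year}|{stage}"


def _stage_order(meta: pd.DataFrame) -> list[str]:
    # library_meta rows are emitted in design stage order
    seen: list[str] = []
    for s in meta["stage"]:
        if s not in seen:
            seen.append(s)
    return seen


def assigned_counts(bundle: Bundle) -> pd.DataFrame:
    """Per-library assigned counts after proportional multi-read rescue."""
    groups_by_lib: dict[str, list] = {}
    for _, row in bundle.multiread_groups.iterrows():
        groups_by_lib.setdefault(row["library"], []).append(
            (str(row["candidates"]).split(";"), float(row["multiplicity"]))
        )
    out = {}
    for lib in bundle.unique_counts.columns:
        out[lib] = assign_multireads(
            bundle.unique_counts[lib].to_dict(), groups_by_lib.get(lib, [])
        )
    return pd.DataFrame(out).reindex(bundle.unique_counts.index)


def condition_log_means(
    matrix: pd.DataFrame, meta: pd.DataFrame, pseudo: float = 1.0
) -> pd.DataFrame:
    """log2(value + pseudo) per library, averaged into condition cells."""
    log2 = np.log2(matrix + pseudo)
    cols = {}
    for (region, year, stage), sub in meta.groupby(
        ["region", "year", "stage"], sort=True
    ):
        cols[_cell_label(region, year, stage)] = log2[sub["library"]].mean(axis=1)
    return pd.DataFrame(cols)


def metabolite_log_means(records: pd.DataFrame, pseudo: float = 0.0) -> pd.DataFrame:
    """log2 replicate-mean concentration per compound and condition cell."""
    means = (
        records.groupby(["compound", "region", "year", "stage"])[
            "concentration_ug_l"
        ]
        .mean()
        .reset_index()
    )
    means["cell"] = [
        _cell_label(r, y, s)
        for r, y, s in zip(means["region"], means["year"], means["stage"])
    ]
    wide = means.pivot(index="compound", columns="cell", values="concentration_ug_l")
    return np.log2(wide + pseudo)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest."""
    config.validate()
    bundle_dir = Path(config.bundle_dir)
    required = [
        "transcripts.tsv", "library_meta.tsv", "unique_counts.tsv",
        "multiread_groups.tsv", "metabolites.csv", "thresholds.csv",
        "qpcr.csv", "climate.csv",
    ]
    missing = [f for f in required if not (bundle_dir / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"bundle directory {bundle_dir} is missing input files: {missing}"
        )
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = Bundle.read(bundle_dir)
    meta = bundle.library_meta
    stage_order = _stage_order(meta)
    regions = list(dict.fromkeys(meta["region"]))
    years = list(dict.fromkeys(meta["year"]))
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, sep: str = "\t", index: bool = False):
        path = out_dir / name
        df.to_csv(path, sep=sep, index=index, float_format="%.10g")
        written[name] = path

    t0 = time.time()

    # --- expression -------------------------------------------------------
    counts = assigned_counts(bundle)
    lengths = bundle.transcripts.set_index("transcript")["length_nt"]
    totals = meta.set_index("library")["total_mapped"]
    rpkms = rpkm_matrix(counts, lengths, totals)
    emit("rpkm_matrix.tsv", rpkms.rename_axis("transcript"), index=True)
    log.info("expression: %d transcripts x %d libraries (%.1fs)",
             *rpkms.shape, time.time() - t0)

    # --- regional DEGs per year-stage --------------------------------------
    cond = {
        row["library"]: _cell_label(row["region"], row["year"], row["stage"])
        for _, row in meta.iterrows()
    }
    comparisons = [
        Comparison(
            label=f"{regions[0]}-vs-{regions[1]}@{stage}/{year}",
            condition_a=_cell_label(regions[0], year, stage),
            condition_b=_cell_label(regions[1], year, stage),
        )
        for year in years
        for stage in stage_order
        if len(regions) >= 2
    ]
    degs = call_degs(
        counts, cond, comparisons,
        alpha=config.alpha, lfc_threshold=config.lfc_threshold,
    )
    emit("deg_results.tsv", degs)

    # --- profile analysis ---------------------------------------------------
    expr_cells = condition_log_means(rpkms, meta, config.log_pseudocount)
    categories = bundle.transcripts.set_index("transcript")["category"]
    pathway_ids = categories[categories.isin(STRUCTURAL_CATEGORIES)].index
    pathway = expr_cells.loc[expr_cells.index.intersection(pathway_ids)]
    varying = pathway[pathway.std(axis=1) > 0]
    scaled = profiles.row_scale(varying)
    emit("scaled_matrix.tsv", scaled.rename_axis("transcript"), index=True)
    dendro = profiles.hierarchical_cluster(scaled)
    (out_dir / "dendrogram.nwk").write_text(dendro.newick + "\n")
    written["dendrogram.nwk"] = out_dir / "dendrogram.nwk"

    stage_means = pd.DataFrame(
        {
            stage: rpkms[meta.loc[meta["stage"] == stage, "library"]].mean(axis=1)
            for stage in stage_order
        }
    )
    detected = stage_means > 0
    trends = profiles.classify_trends(
        np.log2(stage_means + config.log_pseudocount),
        detected,
        r_threshold=config.r_trend,
    )
    emit("trend_classes.tsv", trends)

    ugt_ids = categories[categories == "UGT"].index
    ugt = expr_cells.loc[expr_cells.index.intersection(ugt_ids)]
    ugt = ugt[ugt.std(axis=1) > 0]
    clusters = pd.DataFrame(columns=["transcript", "cluster", "upward"])
    if len(ugt) >= config.kmeans_k:
        stage_idx = [stage_order.index(c.split("|")[2]) for c in ugt.columns]
        km = profiles.kmeans_trends(
            profiles.row_scale(ugt), config.kmeans_k, config.kmeans_seed,
            stage_index=stage_idx, r_upward=config.r_trend,
        )
        clusters = pd.DataFrame(
            {
                "transcript": km.labels.index,
                "cluster": km.labels.to_numpy(),
                "upward": [t in set(km.upward_members) for t in km.labels.index],
            }
        )
    emit("clusters.tsv", clusters)

    # --- metabolites ---------------------------------------------------------
    emit("totals.csv", metab_mod.totals_by_form(bundle.metabolites), sep=",")
    emit("oav.csv", metab_mod.oav_table(bundle.metabolites, bundle.thresholds),
         sep=",")
    emit(
        "anova_duncan.csv",
        metab_mod.anova_duncan_table(bundle.metabolites, alpha=config.alpha),
        sep=",",
    )

    # --- gene-metabolite integration ----------------------------------------
    met_cells = metabolite_log_means(bundle.metabolites)
    met_cells = met_cells[expr_cells.columns]
    corr = integration.correlation_table(
        varying, met_cells.dropna(),
        mode=config.correlation_mode, stage_order=stage_order,
    )
    emit("gene_metabolite_corr.tsv", corr)
    candidates = integration.nominate_candidates(
        corr, degs, r_min=config.r_network, alpha=config.alpha,
        categories=categories.to_dict(),
    )
    emit("candidates.tsv", candidates)

    # --- co-expression networks ----------------------------------------------
    tf_ids = categories[categories == "TF"].index
    tf_cells = expr_cells.loc[expr_cells.index.intersection(tf_ids)]
    tf_cells = tf_cells[tf_cells.std(axis=1) > 0]
    edges = coexpression.correlation_edges(
        varying, tf_cells,
        threshold=config.r_network, inclusive=config.network_inclusive,
    )
    coexpression.export_network(
        edges, out_dir, basename="tf_network",
        node_attributes={t: {"category": categories.get(t, "")}
                         for e in edges for t in (e.source, e.target)},
    )
    for name in ("tf_network.sif", "tf_network.graphml",
                 "tf_network_node_attributes.tsv",
                 "tf_network_edge_attributes.tsv"):
        written[name] = out_dir / name

    anchors = list(config.anchors)
    if not anchors:
        anchors = list(candidates["gene"].head(2))
    if not anchors:
        anchors = list(varying.index[:2])
    anchors = [a for a in anchors if a in varying.index]
    if anchors:
        ripening_ids = categories[categories == "ripening"].index
        rip_cells = expr_cells.loc[expr_cells.index.intersection(ripening_ids)]
        rip_cells = rip_cells[rip_cells.std(axis=1) > 0]
        network = coexpression.build_anchored_network(
            varying.loc[anchors], tf_cells, rip_cells,
            threshold=config.r_network, inclusive=config.network_inclusive,
        )
        coexpression.export_network(network, out_dir, basename="anchored_network")
        for name in ("anchored_network.sif", "anchored_network.graphml",
                     "anchored_network_node_attributes.tsv",
                     "anchored_network_edge_attributes.tsv"):
            written[name] = out_dir / name

    # --- qPCR validation -------------------------------------------------------
    qexpr = qpcr_mod.expression_table(bundle.qpcr)
    emit("qpcr_expression.tsv", qexpr)
    val_rows = []
    if not qexpr.empty:
        qexpr = qexpr.copy()
        qexpr["cell"] = qexpr["sample"].str.rsplit("_", n=1).str[0].str.replace(
            "_", "|", regex=False
        )
        cell_map = {
            _cell_label(r, y, s).replace("|", "|"): _cell_label(r, y, s)
            for r, y, s in meta[["region", "year", "stage"]].itertuples(index=False)
        }
        per_cell = qexpr.groupby(["gene", "cell"])["expression"].mean()
        expr_cells_rpkm = condition_log_means(rpkms, meta, 0.0)  # log2 RPKM
        for gene in per_cell.index.get_level_values("gene").unique():
            if gene not in rpkms.index:
                continue
            series = per_cell.loc[gene]
            cells = [c for c in series.index if cell_map.get(c) in expr_cells_rpkm.columns]
            if len(cells) < 3:
                continue
            q = series.loc[cells].to_numpy()
            r_vals = np.power(
                2.0, expr_cells_rpkm.loc[gene, [cell_map[c] for c in cells]].to_numpy()
            )
            try:
                res = qpcr_mod.validate_against_rpkm(
                    q, r_vals, gene=gene, r2_threshold=config.r2_qpcr
                )
            except ValueError:
                continue
            val_rows.append(asdict(res))
    emit("validation.tsv", pd.DataFrame(
        val_rows, columns=["gene", "n", "r_log", "r2_log", "r_raw", "r2_raw", "passed"]
    ))

    # --- climate -----------------------------------------------------------------
    clim = climate_mod.load_climate(bundle_dir / "climate.csv")
    emit("climate_summary.tsv", climate_mod.summarize_all(clim))

    manifest = {
        "config": asdict(config),
        "alignment_provenance": ALIGNMENT_PROVENANCE,
        "outputs": {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(written.items())
        },
        "n_outputs": len(written),
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    log.info("pipeline complete: %d outputs in %.1fs", len(written),
             time.time() - t0)
    return manifest
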