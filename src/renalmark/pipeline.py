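"""End-to-end orchestration: chain the stages and emit a run report.

The full chain mirrors the biomarker workflow: serum reporter-ion
quantification -> tissue differential expression -> median-centered
two-way clustering of the differential genes -> seed-target indexing
-> miRNA/mRNA functional pairs -> immunostain group statistics ->
cross-platform concordance (proteins called up in serum whose genes
are also called up in tissue, or down/down).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .clustering import hcluster, median_center, write_cdt_gtr
from .config import PipelineConfig, load_config
from .dataio import read_fasta_utrs, read_gmt, read_matrix
from .diffexpr import DifferentialCall, calls_to_frame, de_test
from .funcpairs import functional_pairs, term_enrichment
from .groupstats import anova_from_raw, lsd_pairwise
from .itraq import (
    ProteinRatioRecord,
    ReporterRunTable,
    call_de_proteins,
    normalize_run,
    protein_ratios,
    records_to_frame,
)
from .seed_targets import build_target_index, read_families

__all__ = ["RunReport", "run_full", "concordance", "read_reporter_run"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("itraq", "de", "cluster", "targets", "pairs", "groupstats", "concordance")


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    config: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    stages_run: list = field(default_factory=list)
    protein_calls: pd.DataFrame | None = None
    gene_calls: pd.DataFrame | None = None
    mirna_calls: pd.DataFrame | None = None
    functional_pairs: pd.DataFrame | None = None
    cluster_files: dict = field(default_factory=dict)
    group_stats: dict = field(default_factory=dict)
    concordance_table: pd.DataFrame | None = None
    counts: dict = field(default_factory=dict)

    def save(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "protein_calls": self.protein_calls,
            "gene_calls": self.gene_calls,
            "mirna_calls": self.mirna_calls,
            "functional_pairs": self.functional_pairs,
            "concordance": self.concordance_table,
        }
        manifest_out = {}
        for name, df in tables.items():
            if df is not None:
                path = outdir / f"{name}.tsv"
                df.to_csv(path, sep="\t", index=False)
                manifest_out[name] = str(path)
        summary = {
            "config": self.config,
            "stages_run": self.stages_run,
            "counts": self.counts,
            "inputs": {k: str(v) for k, v in self.manifest.items()},
            "outputs": manifest_out,
            "cluster_files": {k: str(v) for k, v in self.cluster_files.items()},
            "group_stats": self.group_stats,
        }
        report_path = outdir / "report.json"
        with open(report_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return report_path


def read_reporter_run(table_path, channel_map_path, run_id: str) -> ReporterRunTable:
    """Read a protein x channel TSV plus its channel->group map TSV.

    The intensity table's first two columns are protein accession and
    gene symbol, followed by one column per channel. The map file has
    two columns: channel, group.
    """
    df = pd.read_csv(table_path, sep="\t", dtype={0: str, 1: str})
    prot_col, gene_col = df.columns[0], df.columns[1]
    intensities = df.set_index(prot_col)[df.columns[2:]].astype(float)
    gene_symbols = dict(zip(df[prot_col], df[gene_col]))
    cmap_df = pd.read_csv(channel_map_path, sep="\t", dtype=str)
    cmap = dict(zip(cmap_df.iloc[:, 0], cmap_df.iloc[:, 1]))
    return ReporterRunTable(run_id=run_id, intensities=intensities,
                            channel_to_group=cmap, gene_symbols=gene_symbols)


def concordance(
    protein_records: list[ProteinRatioRecord],
    gene_calls: list[DifferentialCall],
) -> pd.DataFrame:
    """Cross-platform agreement table keyed by gene symbol.

    A gene is concordant when the serum protein is up in all three
    comparisons and the tissue gene passes as up, or both platforms
    call down. One row per concordant symbol with the direction on
    each platform.
    """
    gene_by_id = {c.feature: c for c in gene_calls}
    rows = []
    for rec in protein_records:
        call = gene_by_id.get(rec.gene)
        if call is None or not call.passes:
            continue
        if rec.rcc_upregulated and call.direction == "up":
            serum_dir = tissue_dir = "Up"
        elif rec.rcc_downregulated and call.direction == "down":
            serum_dir = tissue_dir = "Down"
        else:
            continue
        rows.append(
            {
                "gene": rec.gene,
                "protein": rec.protein,
                "ratio_RH": rec.ratio_RH,
                "ratio_RC": rec.ratio_RC,
                "ratio_RM": rec.ratio_RM,
                "tissue_fc": call.fc,
                "tissue_p": call.p_value,
                "tissue_genes": tissue_dir,
                "serum_proteins": serum_dir,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "protein", "ratio_RH", "ratio_RC", "ratio_RM",
                 "tissue_fc", "tissue_p", "tissue_genes", "serum_proteins"],
    )


def run_full(
    config: PipelineConfig | str,
    inputs: dict,
    outdir,
    stages: tuple = ALL_STAGES,
) -> RunReport:
    """Run the enabled stages in dependency order and write a report.

    `inputs` is a manifest of file paths and group labels. Required
    keys per stage:

    itraq       : itraq_run1, itraq_map1, itraq_run2, itraq_map2
    de          : gene_matrix, gene_annotation, case_group, control_group
                  (optionally mirna_matrix, mirna_annotation for the
                  miRNA side, reusing the same group labels)
    cluster     : (uses the DE stage's passing genes)
    targets     : utr_fasta, families
    pairs       : (uses de + targets outputs)
    groupstats  : iod_table  — TSV with sample, group, value columns
    concordance : (uses itraq + de outputs)

    Missing inputs for an enabled stage raise before any computation.
    An empty `stages` tuple yields an empty report.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    required = {
        "itraq": ["itraq_run1", "itraq_map1", "itraq_run2", "itraq_map2"],
        "de": ["gene_matrix", "gene_annotation", "case_group", "control_group"],
        "targets": ["utr_fasta", "families"],
        "groupstats": ["iod_table"],
    }
    deps = {"cluster": ["de"], "pairs": ["de", "targets"], "concordance": ["itraq", "de"]}
    for stage in stages:
        for key in required.get(stage, []):
            if key not in inputs:
                raise ValueError(f"stage {stage!r} enabled but input {key!r} missing")
        for dep in deps.get(stage, []):
            if dep not in stages:
                raise ValueError(f"stage {stage!r} requires stage {dep!r} to be enabled")

    report = RunReport(
        config={k: getattr(config, k) for k in vars(config)},
        manifest={k: v for k, v in inputs.items()},
    )

    protein_records: list[ProteinRatioRecord] = []
    gene_call_list: list[DifferentialCall] = []
    mirna_call_list: list[DifferentialCall] = []
    gene_matrix = None

    if "itraq" in stages:
        run1 = read_reporter_run(inputs["itraq_run1"], inputs["itraq_map1"], "run1")
        run2 = read_reporter_run(inputs["itraq_run2"], inputs["itraq_map2"], "run2")
        protein_records = protein_ratios(
            normalize_run(run1), normalize_run(run2), average=config.ratio_average
        )
        call_de_proteins(protein_records, config)
        report.protein_calls = records_to_frame(protein_records)
        report.counts["proteins_quantified"] = len(protein_records)
        report.counts["proteins_rcc_up"] = int(sum(r.rcc_upregulated for r in protein_records))
        report.stages_run.append("itraq")
        logger.info("itraq: %d proteins, %d carcinoma-up",
                    len(protein_records), report.counts["proteins_rcc_up"])

    if "de" in stages:
        gene_matrix = read_matrix(inputs["gene_matrix"], inputs["gene_annotation"])
        gene_call_list = de_test(gene_matrix, inputs["case_group"], inputs["control_group"], config)
        report.gene_calls = calls_to_frame(gene_call_list)
        report.counts["genes_tested"] = len(gene_call_list)
        report.counts["genes_up"] = sum(c.passes and c.direction == "up" for c in gene_call_list)
        report.counts["genes_down"] = sum(c.passes and c.direction == "down" for c in gene_call_list)
        if "mirna_matrix" in inputs:
            mirna_matrix = read_matrix(inputs["mirna_matrix"], inputs["mirna_annotation"], unit="RPM")
            mirna_call_list = de_test(
                mirna_matrix,
                inputs.get("mirna_case_group", inputs["case_group"]),
                inputs.get("mirna_control_group", inputs["control_group"]),
                config,
            )
            report.mirna_calls = calls_to_frame(mirna_call_list)
            report.counts["mirnas_down"] = sum(
                c.passes and c.direction == "down" for c in mirna_call_list
            )
        report.stages_run.append("de")
        logger.info("de: %d genes tested, %d up / %d down pass",
                    report.counts["genes_tested"], report.counts["genes_up"],
                    report.counts["genes_down"])

    if "cluster" in stages:
        passing = [c.feature for c in gene_call_list if c.passes]
        if len(passing) >= 2 and gene_matrix is not None:
            sub = gene_matrix.values.loc[passing]
            centered = sub.sub(sub.median(axis=1), axis=0)
            gene_tree = hcluster(centered, axis="genes")
            sample_tree = hcluster(centered, axis="samples")
            report.cluster_files = write_cdt_gtr(centered, gene_tree, sample_tree,
                                                 outdir / "clustered")
            report.counts["genes_clustered"] = len(passing)
        else:
            logger.info("cluster: fewer than 2 passing genes; skipped")
            report.counts["genes_clustered"] = 0
        report.stages_run.append("cluster")

    index = None
    if "targets" in stages:
        utrs = read_fasta_utrs(inputs["utr_fasta"])
        families = read_families(inputs["families"])
        index = build_target_index(utrs, families,
                                   min_site_type=inputs.get("min_site_type", "7mer-A1"))
        report.counts["families_indexed"] = len(families)
        report.counts["target_counts"] = {f: index.count(f) for f in index.families}
        report.stages_run.append("targets")

    if "pairs" in stages and index is not None and gene_matrix is not None:
        background = list(gene_matrix.values.index)
        pair_report = functional_pairs(gene_call_list, mirna_call_list, index,
                                       background, config)
        report.functional_pairs = pair_report.to_frame()
        report.counts["functional_pair_families"] = len(pair_report.rows)
        report.stages_run.append("pairs")

    if "groupstats" in stages:
        iod = pd.read_csv(inputs["iod_table"], sep="\t")
        res = anova_from_raw(iod["value"].to_numpy(), iod["group"].to_numpy())
        lsd = lsd_pairwise(res)
        report.group_stats = {
            "F": res.F,
            "df_between": res.df_between,
            "df_within": res.df_within,
            "p_value": res.p_value,
            "lsd": [
                {"pair": f"{r.group_a} vs {r.group_b}", "t": r.t, "p": r.p_value}
                for r in lsd
            ],
        }
        res.summary_frame().to_csv(outdir / "iod_group_summaries.tsv", sep="\t", index=False)
        report.stages_run.append("groupstats")

    if "concordance" in stages:
        report.concordance_table = concordance(protein_records, gene_call_list)
        report.counts["concordant_genes"] = len(report.concordance_table)
        report.stages_run.append("concordance")

    report.save(outdir)
    return report
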