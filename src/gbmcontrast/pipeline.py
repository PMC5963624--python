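"""Single-entry orchestration: burden -> contrast -> expression -> CNV
-> integration, from a flat config, with a consolidated summary.

``run_pipeline`` writes every stage's outputs under one run directory
plus a ``summary.json`` reproducing the headline count panel (totals,
mutated-gene sets, hypermutation, exclusivity, shared variants, DEG
Venn regions, CNV segments) and the three contingency tests.  Stages
that cannot run on a given input (no expression file, a degenerate
table) are skipped with an explicit reason rather than failing the
run; a MANIFEST file lists the stages completed.
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from . import burden as gburden
from . import cnv as gcnv
from . import contrast as gcontrast
from . import expression as gexpr
from . import io as gio

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one run.

    Threshold defaults mirror the published analysis: hypermutation at
    more than 50 variants per gene, recurrent genes at more than 4
    variants, DEG FDR 0.05, CNV cut-off 1.0 (tumor vs normal) and 0.8
    (group contrast) with a 0.5 SD band.
    """

    variants: str
    manifest: str
    out_dir: str
    expression: Optional[str] = None
    coverage_dir: Optional[str] = None
    normal_coverage: Optional[str] = None
    gene_model: Optional[str] = None
    variant_format: str = "tsv"
    group_1: str = "S"
    group_2: str = "L"
    hypermutation_threshold: int = 50
    recurrent_min_variants: int = 4
    alpha_fdr: float = 0.05
    cnv_cutoff_tumor_normal: float = 1.0
    cnv_cutoff_group: float = 0.8
    cnv_sd_band: float = 0.5
    cnv_min_bins: int = 5
    cnv_pseudocount: float = 0.5
    test_method: str = "chi2"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hypermutation_threshold", "recurrent_min_variants"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("alpha_fdr", "cnv_cutoff_tumor_normal", "cnv_cutoff_group",
                     "cnv_sd_band"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Flat key-value TOML config; keyword overrides win."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the summary dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    summary: dict = {"config": asdict(config), "skipped": {}}
    g1, g2 = config.group_1, config.group_2

    def stage_done(name: str, t0: float, detail: str = "") -> None:
        completed.append(name)
        logger.info("stage %s done in %.2fs %s", name, time.time() - t0, detail)

    try:
        # ---- inputs -----------------------------------------------------
        t0 = time.time()
        manifest = gio.read_manifest(config.manifest)
        records = gio.read_variants(config.variants, format=config.variant_format)
        sequenced = sorted({r.sample_id for r in records})
        wes_manifest = manifest.subset(sequenced) if sequenced else manifest
        stage_done("io", t0, f"({len(records)} records, {len(manifest)} samples)")

        # ---- burden -----------------------------------------------------
        t0 = time.time()
        summaries = gburden.summarize_burden(records, wes_manifest)
        matrix = gburden.build_gene_burden_matrix(records, wes_manifest)
        hyper = gburden.flag_hypermutated(matrix, config.hypermutation_threshold)
        gburden.write_burden_summary(summaries, out / "burden_summary.tsv")
        gburden.write_gene_burden(matrix, hyper, out / "gene_burden.tsv")
        summary["burden"] = {
            s.group: {
                "n_total": s.n_total,
                "n_coding": s.n_coding,
                "n_deleterious": s.n_deleterious,
            }
            for s in summaries
        }
        stage_done("burden", t0)

        # ---- contrast ---------------------------------------------------
        t0 = time.time()
        if records and g1 in wes_manifest.groups and g2 in wes_manifest.groups:
            report = gcontrast.build_contrast_report(
                records, matrix, wes_manifest, g1, g2,
                hypermutation_threshold=config.hypermutation_threshold,
                min_recurrent_variants=config.recurrent_min_variants,
                method=config.test_method,
            )
            report.write_json(out / "contrast_report.json")
            gcontrast.write_tests(report.tests, out / "tests.tsv")
            summary["contrast"] = {
                "mutated_genes": {g: len(report.mutated_genes[g]) for g in (g1, g2)},
                "union_size": report.union_size,
                "exclusive_genes": {
                    g: len(report.exclusive_genes[g]) for g in (g1, g2)
                },
                "hypermutated": {g: len(report.hypermutated[g]) for g in (g1, g2)},
                "recurrent_genes": {
                    g: len(report.recurrent_genes[g]) for g in (g1, g2)
                },
                "exclusive_shared_variants": {
                    g: len(report.exclusive_shared_variants[g]) for g in (g1, g2)
                },
                "universal_variants": len(report.universal_variants),
                "tests": [
                    {"name": t.name, "method": t.method,
                     "statistic": t.statistic, "p_value": t.p_value}
                    for t in report.tests
                ],
            }
            if not report.tests:
                summary["skipped"]["contingency_tests"] = "degenerate table"
        else:
            report = None
            summary["skipped"]["contrast"] = "no variant records for both groups"
        stage_done("contrast", t0)

        # ---- expression -------------------------------------------------
        expr = None
        deg_tables = {}
        if config.expression:
            t0 = time.time()
            expr = gio.read_expression(config.expression)
            pairs = {"SL": ("S", "L"), "SM": ("S", "M"), "ML": ("M", "L")}
            try:
                for label, pair in pairs.items():
                    deg_tables[label] = gexpr.differential_expression(
                        expr, manifest, pair, alpha_fdr=config.alpha_fdr
                    )
                    deg_tables[label].write(out / f"deg_{label}.tsv")
                deg_m_rest = gexpr.differential_expression(
                    expr, manifest, ("M", "rest"), alpha_fdr=config.alpha_fdr
                )
                deg_m_rest.write(out / "deg_M_vs_rest.tsv")
                venn = gexpr.venn_partition(
                    deg_tables["SL"], deg_tables["SM"], deg_tables["ML"]
                )
                venn.write(out / "venn_partition.tsv")
                common = gexpr.common_degs(deg_m_rest, deg_tables["SL"])
                summary["expression"] = {
                    "venn_total": venn.total,
                    "venn_regions": venn.region_counts,
                    "m_vs_rest_degs": len(deg_m_rest.significant_genes),
                    "m_common_with_sl": len(common),
                }
            except ValueError as exc:
                summary["skipped"]["expression"] = str(exc)
            stage_done("expression", t0)
        else:
            summary["skipped"]["expression"] = "no expression input"

        # ---- cnv --------------------------------------------------------
        gene_states: dict[str, dict[str, str]] = {}
        if config.coverage_dir and config.normal_coverage:
            t0 = time.time()
            covdir = Path(config.coverage_dir)
            normal = gio.read_coverage(config.normal_coverage)
            tracks = {
                p.stem: gio.read_coverage(p)
                for p in sorted(covdir.glob("*.tsv"))
                if p.resolve() != Path(config.normal_coverage).resolve()
            }
            by_group: dict[str, list] = {}
            for sid, track in tracks.items():
                grp = manifest.group_of(sid)
                by_group.setdefault(grp, []).append(track)
            all_tumor = [t for ts in by_group.values() for t in ts]
            tn_track = gcnv.log2_ratio_track(
                all_tumor, normal, pseudocount=config.cnv_pseudocount
            )
            tn_segments = gcnv.call_segments(
                tn_track, config.cnv_cutoff_tumor_normal,
                config.cnv_sd_band, config.cnv_min_bins,
            )
            gcnv.write_segments_bed(tn_segments, out / "segments_tumor_normal.bed")
            summary["cnv"] = {
                "tumor_normal_aberrant_segments": sum(
                    1 for s in tn_segments if s.state != "neutral"
                ),
            }
            if g1 in by_group and g2 in by_group:
                contrast_track = gcnv.group_contrast_track(
                    by_group[g1], by_group[g2], pseudocount=config.cnv_pseudocount
                )
                gc_segments = gcnv.call_segments(
                    contrast_track, config.cnv_cutoff_group,
                    config.cnv_sd_band, config.cnv_min_bins,
                )
                gcnv.write_segments_bed(gc_segments, out / "segments_group.bed")
                summary["cnv"]["group_contrast_aberrant_segments"] = sum(
                    1 for s in gc_segments if s.state != "neutral"
                )
                if config.gene_model:
                    genes_model = gio.read_gene_model(config.gene_model)
                    gene_states = gcnv.gene_cnv_states(
                        {g1: gc_segments, g2: [
                            gcnv.CnvSegment(s.chrom, s.start, s.end,
                                            {"amplified": "deleted",
                                             "deleted": "amplified",
                                             "neutral": "neutral"}[s.state],
                                            -s.mean_log2, s.sd_log2, s.n_bins)
                            for s in gc_segments
                        ]},
                        genes_model,
                    )
                    annotated = gcnv.annotate_segments(
                        [s for s in gc_segments if s.state != "neutral"], genes_model
                    )
                    with open(out / "cnv_genes.tsv", "w", encoding="utf-8") as fh:
                        fh.write("chrom\tstart\tend\tstate\tgenes\n")
                        for seg, genes in annotated:
                            fh.write(
                                f"{seg.chrom}\t{seg.start}\t{seg.end}\t"
                                f"{seg.state}\t{','.join(genes)}\n"
                            )
                    if expr is not None:
                        conc = gcnv.cnv_expression_concordance(
                            gene_states, expr, manifest, g1, g2
                        )
                        conc.to_csv(out / "concordance.tsv", sep="\t")
            stage_done("cnv", t0)
        else:
            summary["skipped"]["cnv"] = "no coverage inputs"

        # ---- integration ------------------------------------------------
        if report is not None:
            t0 = time.time()
            noteworthy = sorted(
                set().union(*report.hypermutated.values())
                | {g for lst in report.recurrent_genes.values() for g, _ in lst}
                | set().union(*(set(m) for m in gene_states.values()))
                if gene_states
                else set().union(*report.hypermutated.values())
                | {g for lst in report.recurrent_genes.values() for g, _ in lst}
            )
            integrated = gexpr.integrate(
                matrix, report.hypermutated, gene_states, expr,
                wes_manifest, noteworthy,
            )
            integrated.to_csv(out / "integrated_report.tsv", sep="\t")
            summary["integrated_genes"] = len(integrated)
            stage_done("integrate", t0)

        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1)
        completed.append("summary")
        return summary
    finally:
        with open(out / "MANIFEST", "w", encoding="utf-8") as fh:
            fh.write("\n".join(completed) + "\n")
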