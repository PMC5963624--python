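"""Differential expression partitioning and mutation/CNV integration.

The published study screened FPKM expression across the three RFS
groups and partitioned the significant genes by which pairwise group
comparison drives them (a three-set Venn over S-vs-L, S-vs-M and
M-vs-L).  The engine here is deliberately simple and replaceable:
Welch's t-test on log2(FPKM + 1) for pairwise comparisons, one-way
ANOVA on the same transform for the three-group screen, and
Benjamini-Hochberg FDR control at 0.05.  The partition and integration
logic is engine-agnostic: a DegTable can equally be imported from any
external differential-expression tool via TSV.

Degenerate genes (zero variance on both sides) are resolved
deterministically: p = 1 when the side means are equal, p = 0 when
they differ.  This makes recovery of noise-free planted signal exact
and leaves the stochastic path untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .burden import GeneBurdenMatrix
from .cohort import CohortManifest, ExpressionMatrix

Comparison = tuple[str, str]  # ("S","L"), ("M","rest"), ...


def bh_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DegTable:
    """Per-gene differential-expression results for one comparison.

    ``frame`` columns: mean_a, mean_b (mean FPKM per side), log2fc
    (difference of group means of log2(FPKM+1), side a minus side b),
    p_value, q_value, significant.  Index is the gene symbol.
    """

    comparison: tuple[str, str]
    frame: pd.DataFrame
    alpha_fdr: float = 0.05

    @property
    def significant_genes(self) -> set[str]:
        return set(self.frame.index[self.frame["significant"]])

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    def write(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def _row_tolerance(*arrays: np.ndarray) -> np.ndarray:
    """Per-row absolute tolerance below which differences and standard
    deviations are treated as zero (floating-point rounding of means
    over identical values otherwise manufactures tiny t statistics)."""
    scale = np.max([np.abs(a).max(axis=1, initial=0.0) for a in arrays], axis=0)
    return 1e-9 * (scale + 1.0)


def _welch_with_degenerate(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Welch t-test over rows, with deterministic
    handling of (numerically) zero-variance-on-both-sides rows."""
    with np.errstate(all="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    tol = _row_tolerance(a, b)
    sd_a = a.std(axis=1, ddof=1)
    sd_b = b.std(axis=1, ddof=1)
    diff = np.abs(a.mean(axis=1) - b.mean(axis=1))
    degenerate = (sd_a <= tol) & (sd_b <= tol)
    p[degenerate & (diff <= tol)] = 1.0
    p[degenerate & (diff > tol)] = 0.0
    p[np.isnan(p)] = 1.0  # any residual undefined case: not significant
    return p


def _anova_with_degenerate(groups: list[np.ndarray]) -> np.ndarray:
    with np.errstate(all="ignore"):
        res = stats.f_oneway(*groups, axis=1)
        p = np.asarray(res.pvalue, dtype=float)
    tol = _row_tolerance(*groups)
    within_sd = np.max([g.std(axis=1, ddof=1) for g in groups], axis=0)
    means = np.stack([g.mean(axis=1) for g in groups])
    spread = means.max(axis=0) - means.min(axis=0)
    degenerate = within_sd <= tol
    p[degenerate & (spread <= tol)] = 1.0
    p[degenerate & (spread > tol)] = 0.0
    p[np.isnan(p)] = 1.0
    return p


def _side_samples(manifest: CohortManifest, side: str) -> list[str]:
    if side == "rest":
        raise ValueError("'rest' is only valid as the second side")
    return manifest.samples_in(side)


def differential_expression(
    expr: ExpressionMatrix,
    manifest: CohortManifest,
    comparison: Comparison,
    alpha_fdr: float = 0.05,
) -> DegTable:
    """Pairwise DE screen on log2(FPKM + 1) with BH FDR control.

    ``comparison`` is an ordered pair of group labels, or
    ``(group, "rest")`` for a one-vs-pooled-others screen.  Each side
    needs at least two samples.
    """
    side_a, side_b = comparison
    samples_a = _side_samples(manifest, side_a)
    if side_b == "rest":
        samples_b = [s for s in manifest.sample_ids if s not in samples_a]
    else:
        samples_b = manifest.samples_in(side_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"comparison {comparison}: each side needs >= 2 samples "
            f"(got {len(samples_a)} vs {len(samples_b)})"
        )
    missing = (set(samples_a) | set(samples_b)) - set(expr.samples)
    if missing:
        raise ValueError(f"samples missing from expression matrix: {sorted(missing)}")

    fpkm = expr.values
    log_a = np.log2(fpkm[samples_a].to_numpy(dtype=float) + 1.0)
    log_b = np.log2(fpkm[samples_b].to_numpy(dtype=float) + 1.0)
    p = _welch_with_degenerate(log_a, log_b)
    q = bh_qvalues(p)
    frame = pd.DataFrame(
        {
            "mean_a": fpkm[samples_a].mean(axis=1),
            "mean_b": fpkm[samples_b].mean(axis=1),
            "log2fc": log_a.mean(axis=1) - log_b.mean(axis=1),
            "p_value": p,
            "q_value": q,
            "significant": q < alpha_fdr,
        },
        index=fpkm.index,
    )
    return DegTable(comparison=(side_a, side_b), frame=frame, alpha_fdr=alpha_fdr)


def three_group_screen(
    expr: ExpressionMatrix,
    manifest: CohortManifest,
    alpha_fdr: float = 0.05,
) -> DegTable:
    """One-way ANOVA across all manifest groups on log2(FPKM + 1)."""
    groups = manifest.groups
    if len(groups) < 2:
        raise ValueError("three-group screen needs >= 2 groups")
    fpkm = expr.values
    arrays = []
    for g in groups:
        samples = manifest.samples_in(g)
        if len(samples) < 2:
            raise ValueError(f"group {g} has < 2 samples")
        arrays.append(np.log2(fpkm[samples].to_numpy(dtype=float) + 1.0))
    p = _anova_with_degenerate(arrays)
    q = bh_qvalues(p)
    frame = pd.DataFrame(
        {
            "mean_a": fpkm.mean(axis=1),
            "mean_b": np.nan,
            "log2fc": np.nan,
            "p_value": p,
            "q_value": q,
            "significant": q < alpha_fdr,
        },
        index=fpkm.index,
    )
    return DegTable(comparison=("anova", "all"), frame=frame, alpha_fdr=alpha_fdr)


_REGIONS = ("SL", "SM", "ML", "SL&SM", "SL&ML", "SM&ML", "SL&SM&ML")


@dataclass
class VennPartition:
    """Seven-region partition of the union of three significant sets.

    Region labels name the comparisons a gene is significant in;
    single labels are exclusive regions (e.g. ``"SL"`` is
    S-vs-L-only).  Region counts sum to the size of the union.
    """

    membership: pd.DataFrame  # boolean columns SL, SM, ML over the union
    region_counts: dict[str, int]

    @property
    def total(self) -> int:
        return int(len(self.membership))

    def genes_in_region(self, region: str) -> set[str]:
        want = set(region.split("&"))
        m = self.membership
        mask = np.ones(len(m), dtype=bool)
        for label in ("SL", "SM", "ML"):
            mask &= m[label].to_numpy() == (label in want)
        return set(m.index[mask])

    def write(self, path: str | Path) -> None:
        out = self.membership.copy()
        out["region"] = [
            "&".join(l for l in ("SL", "SM", "ML") if row[l])
            for _, row in out.iterrows()
        ]
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def venn_partition(
    deg_sl: DegTable, deg_sm: DegTable, deg_ml: DegTable
) -> VennPartition:
    """Partition the union of significant genes by driving comparison."""
    universes = [set(t.genes) for t in (deg_sl, deg_sm, deg_ml)]
    if not (universes[0] == universes[1] == universes[2]):
        raise ValueError("DEG tables have mismatched gene universes")
    sig = {
        "SL": deg_sl.significant_genes,
        "SM": deg_sm.significant_genes,
        "ML": deg_ml.significant_genes,
    }
    union = sorted(sig["SL"] | sig["SM"] | sig["ML"])
    membership = pd.DataFrame(
        {label: [g in sig[label] for g in union] for label in ("SL", "SM", "ML")},
        index=pd.Index(union, name="gene"),
    )
    counts: dict[str, int] = {}
    for region in _REGIONS:
        want = set(region.split("&"))
        mask = np.ones(len(membership), dtype=bool)
        for label in ("SL", "SM", "ML"):
            mask &= membership[label].to_numpy() == (label in want)
        counts[region] = int(mask.sum())
    return VennPartition(membership=membership, region_counts=counts)


def common_degs(deg_a: DegTable, deg_b: DegTable) -> set[str]:
    """Genes significant in both tables (same gene universe required)."""
    if set(deg_a.genes) != set(deg_b.genes):
        raise ValueError("DEG tables have mismatched gene universes")
    return deg_a.significant_genes & deg_b.significant_genes


def expression_tiers(mean_log_fpkm: pd.Series) -> pd.Series:
    """Low/mid/high tertile tiers of log2(FPKM+1) over the given genes."""
    valid = mean_log_fpkm.dropna()
    if len(valid) == 0:
        return pd.Series("missing", index=mean_log_fpkm.index, dtype=object)
    if len(valid.unique()) < 3:
        tiers = pd.Series("mid", index=valid.index, dtype=object)
    else:
        tiers = pd.cut(
            valid.rank(method="first"), bins=3, labels=["low", "mid", "high"]
        ).astype(object)
        tiers.index = valid.index
    out = pd.Series("missing", index=mean_log_fpkm.index, dtype=object)
    out[valid.index] = tiers
    return out


def integrate(
    matrix: GeneBurdenMatrix,
    hyper_flags: Mapping[str, set[str]],
    cnv_states: Mapping[str, Mapping[str, str]],
    expr: Optional[ExpressionMatrix],
    manifest: CohortManifest,
    genes: Sequence[str],
) -> pd.DataFrame:
    """Integrated per-gene report: variant counts, hypermutation flags,
    CNV state and mean FPKM per group, plus an expression tier.

    ``cnv_states`` maps group -> gene -> {amplified, deleted, neutral}.
    Genes absent from the expression matrix keep their row with FPKM
    fields missing (NaN) and tier "missing"; nothing is dropped.
    """
    groups = manifest.groups
    rows: dict[str, dict] = {}
    for gene in genes:
        row: dict = {}
        for g in groups:
            if gene in matrix.per_group.index and g in matrix.per_group.columns:
                row[f"n_variants_{g}"] = int(matrix.per_group.loc[gene, g])
            else:
                row[f"n_variants_{g}"] = 0
            row[f"hypermutated_{g}"] = gene in hyper_flags.get(g, set())
            row[f"cnv_{g}"] = cnv_states.get(g, {}).get(gene, "neutral")
        rows[gene] = row
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "gene"

    if expr is not None:
        fpkm = expr.values
        for g in groups:
            samples = [s for s in manifest.samples_in(g) if s in fpkm.columns]
            means = fpkm[samples].mean(axis=1) if samples else pd.Series(dtype=float)
            report[f"mean_fpkm_{g}"] = [
                float(means[gene]) if gene in means.index else np.nan
                for gene in report.index
            ]
        overall = np.log2(
            report[[f"mean_fpkm_{g}" for g in groups]].mean(axis=1) + 1.0
        )
        report["expression_tier"] = expression_tiers(overall)
    else:
        for g in groups:
            report[f"mean_fpkm_{g}"] = np.nan
        report["expression_tier"] = "missing"
    return report


def read_deg_table(
    path: str | Path, comparison: tuple[str, str], alpha_fdr: float = 0.05
) -> DegTable:
    """Import an externally computed DEG table (gene, log2fc, p, q)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    required = ["log2fc", "p_value", "q_value"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing DEG columns {missing}")
    for col in ("mean_a", "mean_b"):
        if col not in frame.columns:
            frame[col] = np.nan
    frame["significant"] = frame["q_value"] < alpha_fdr
    return DegTable(comparison=comparison, frame=frame, alpha_fdr=alpha_fdr)
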