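"""Seeded synthetic-cohort generator with planted ground truth.

The study this pipeline re-implements deposited no raw data, so every
quantitative input is emulated here: a 13-patient manifest mirroring
the published cohort (6 Short / 3 Medium / 4 Long RFS, of which
4 S + 4 L were exome-sequenced), per-sample variant calls over a
synthetic genome, an FPKM expression matrix, and windowed coverage
tracks for the tumors plus one blood-DNA control.

Planting is set-exact: group-exclusive genes, recurrent
all-samples-mutated genes, hypermutator genes, group-exclusive
universally shared variant keys, cohort-universal keys, DEG Venn
regions and amplified/deleted regions are constructed verbatim and
returned as GroundTruth in the same vocabulary the pipeline reports,
so running the pipeline on generator output must recover them exactly.
Occurrence-level burden totals are also exact by construction: the
configured per-group totals are reached by distributing background
occurrences multinomially over genes already mutated in both groups,
which cannot perturb any planted set structure.

Background variant sharing is controlled, not emergent: every
background key is drawn in exactly one sample, so universal and
group-shared structures exist only where planted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .cohort import (
    CohortManifest,
    CoverageTrack,
    ExpressionMatrix,
    GeneModel,
    VariantKey,
    VariantRecord,
)


@dataclass(frozen=True)
class CnvRegionSpec:
    """A planted copy-number aberration, in bin coordinates."""

    chrom_index: int
    bin_start: int
    bin_end: int  # exclusive
    fold: float
    groups: tuple[str, ...]  # tumor groups carrying the aberration


# Published cohort layout (sample letter, group, RFS months); the
# starred WES subset is 4 S + 4 L.
_MANIFEST_ENTRIES = [
    ("A", "S", 2), ("B", "S", 3), ("C", "S", 3),
    ("D", "S", 5), ("E", "S", 5), ("F", "S", 5),
    ("G", "M", 16), ("H", "M", 18), ("I", "M", 23),
    ("J", "L", 25), ("K", "L", 30), ("L", "L", 32), ("M", "L", 42),
]
_WES_SAMPLES = ["A", "B", "C", "E", "J", "K", "L", "M"]


@dataclass
class CohortConfig:
    """Everything the generator plants, plus the layout of the
    synthetic genome.  Defaults are desk-scale; ``paper_scale_config``
    returns the preset matching the published counts."""

    seed: int = 0

    # genome layout
    n_chromosomes: int = 3
    chrom_length: int = 30_000_000
    bin_size: int = 100_000
    gene_length: int = 4_500
    gene_spacing: int = 5_000

    # gene universe
    n_genes: int = 300
    n_mutated_s: int = 80
    n_mutated_l: int = 60
    n_mutated_union: int = 110

    # planted variant structures
    n_recurrent: dict = field(default_factory=lambda: {"S": 4, "L": 2})
    recurrent_distinct: int = 5  # distinct variants per recurrent gene (> 4)
    n_hyper: dict = field(default_factory=lambda: {"S": 3, "L": 1})
    hyper_top: dict = field(default_factory=lambda: {"S": 105, "L": 75})
    n_exclusive_shared_variants: dict = field(
        default_factory=lambda: {"S": 5, "L": 2}
    )
    n_universal_variants: int = 3

    # per-occurrence burden targets (exact totals per group)
    total_occurrences: dict = field(default_factory=lambda: {"S": 900, "L": 600})
    n_coding: dict = field(default_factory=lambda: {"S": 630, "L": 432})
    n_deleterious: dict = field(default_factory=lambda: {"S": 468, "L": 318})

    # expression planting
    n_deg_sl_only: int = 10
    n_deg_triple: int = 3
    n_deg_sm_ml: int = 5
    deg_delta: float = 2.0        # S-vs-L shift, log2(FPKM+1) units
    m_noise_sd: float = 4.0       # M-group noise for SL-only genes
    m_shift: float = 8.0          # M-group shift for M-driven genes
    baseline_range: tuple = (3.0, 9.0)
    expression_noise_sd: float = 0.0  # global within-group noise (0 = exact)

    # coverage / CNV
    depth: float = 100.0
    poisson_coverage: bool = True
    cnv_regions: list = field(
        default_factory=lambda: [
            CnvRegionSpec(0, 100, 130, 2.0, ("S", "L")),
            CnvRegionSpec(1, 150, 200, 0.5, ("S", "L")),
            CnvRegionSpec(2, 50, 75, 2.5, ("S",)),
        ]
    )

    def validate(self) -> None:
        if self.n_mutated_union > self.n_genes:
            raise ValueError("mutated-gene union exceeds gene universe")
        if not (max(self.n_mutated_s, self.n_mutated_l)
                <= self.n_mutated_union
                <= self.n_mutated_s + self.n_mutated_l):
            raise ValueError("inconsistent mutated-gene set sizes")
        n_shared = self.n_mutated_s + self.n_mutated_l - self.n_mutated_union
        n_s_only = self.n_mutated_union - self.n_mutated_l
        n_l_only = self.n_mutated_union - self.n_mutated_s
        if self.n_hyper["S"] < self.n_hyper["L"]:
            raise ValueError("L-hypermutated genes are drawn from the S-hyper set")
        if self.n_hyper["S"] + self.n_universal_variants + self.n_deg_total > n_shared:
            raise ValueError("planted shared structures exceed shared-gene capacity")
        if self.n_recurrent["S"] + self.n_exclusive_shared_variants["S"] > n_s_only:
            raise ValueError("planted S-exclusive structures exceed capacity")
        if self.n_recurrent["L"] + self.n_exclusive_shared_variants["L"] > n_l_only:
            raise ValueError("planted L-exclusive structures exceed capacity")
        for g in ("S", "L"):
            if self.n_hyper[g] and self.hyper_top[g] - self.n_hyper[g] + 1 <= 50:
                raise ValueError(f"hyper_top[{g}] too small for {self.n_hyper[g]} genes")
            if not (0 <= self.n_deleterious[g] <= self.n_coding[g]
                    <= self.total_occurrences[g]):
                raise ValueError(f"inconsistent coding/deleterious targets for {g}")
        capacity = (self.chrom_length // self.gene_spacing) * self.n_chromosomes
        if self.n_genes > capacity:
            raise ValueError("gene universe does not fit the synthetic genome")
        if self.recurrent_distinct < 5:
            raise ValueError("recurrent genes need >= 5 distinct variants (> 4 rule)")
        n_bins = self.chrom_length // self.bin_size
        for r in self.cnv_regions:
            if not (0 <= r.bin_start < r.bin_end <= n_bins):
                raise ValueError(f"CNV region {r} outside the binned genome")
            if r.chrom_index >= self.n_chromosomes:
                raise ValueError(f"CNV region {r} on a nonexistent chromosome")

    @property
    def n_deg_total(self) -> int:
        return self.n_deg_sl_only + self.n_deg_triple + self.n_deg_sm_ml


@dataclass
class GroundTruth:
    """Planted structures, in the pipeline's own output vocabulary."""

    mutated_genes: dict[str, set[str]]
    union_genes: set[str]
    exclusive_genes: dict[str, set[str]]
    hypermutated: dict[str, set[str]]
    recurrent_genes: dict[str, dict[str, int]]
    exclusive_shared_variants: dict[str, set[VariantKey]]
    universal_variants: set[VariantKey]
    burden_totals: dict[str, dict[str, int]]
    deg_sl_only: set[str]
    deg_triple: set[str]
    deg_sm_ml: set[str]
    cnv_regions: list[tuple[str, int, int, float, tuple[str, ...]]]

    @property
    def deg_all(self) -> set[str]:
        return self.deg_sl_only | self.deg_triple | self.deg_sm_ml

    @property
    def deg_m_vs_rest(self) -> set[str]:
        return self.deg_triple | self.deg_sm_ml

    def to_json_dict(self) -> dict:
        return {
            "mutated_genes": {g: sorted(s) for g, s in self.mutated_genes.items()},
            "union_genes": sorted(self.union_genes),
            "exclusive_genes": {g: sorted(s) for g, s in self.exclusive_genes.items()},
            "hypermutated": {g: sorted(s) for g, s in self.hypermutated.items()},
            "recurrent_genes": self.recurrent_genes,
            "exclusive_shared_variants": {
                g: sorted(str(k) for k in s)
                for g, s in self.exclusive_shared_variants.items()
            },
            "universal_variants": sorted(str(k) for k in self.universal_variants),
            "burden_totals": self.burden_totals,
            "deg_sl_only": sorted(self.deg_sl_only),
            "deg_triple": sorted(self.deg_triple),
            "deg_sm_ml": sorted(self.deg_sm_ml),
            "cnv_regions": [list(r[:4]) + [list(r[4])] for r in self.cnv_regions],
        }


@dataclass
class SyntheticCohort:
    config: CohortConfig
    manifest: CohortManifest
    wes_samples: list[str]
    records: list[VariantRecord]
    expression: ExpressionMatrix
    coverage: dict[str, CoverageTrack]
    normal: CoverageTrack
    gene_models: list[GeneModel]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gio.write_variants(self.records, outdir / "variants.tsv")
        gio.write_manifest(self.manifest, outdir / "manifest.tsv")
        gio.write_expression(self.expression, outdir / "expression.tsv")
        covdir = outdir / "coverage"
        covdir.mkdir(exist_ok=True)
        for sid, track in self.coverage.items():
            gio.write_coverage(track, covdir / f"{sid}.tsv")
        gio.write_coverage(self.normal, covdir / "normal.tsv")
        gio.write_gene_model(self.gene_models, outdir / "genes.bed")
        with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.truth.to_json_dict(), fh, indent=1, sort_keys=True)

    def content_hash(self) -> str:
        """Deterministic digest of everything the generator produced."""
        h = hashlib.sha256()
        h.update(json.dumps(self.truth.to_json_dict(), sort_keys=True).encode())
        for r in self.records:
            h.update(repr(dataclasses.astuple(r)).encode())
        h.update(self.expression.values.round(10).to_csv().encode())
        for sid in sorted(self.coverage):
            h.update(self.coverage[sid].bins.to_csv().encode())
        h.update(self.normal.bins.to_csv().encode())
        return h.hexdigest()


def _gene_layout(config: CohortConfig) -> list[GeneModel]:
    per_chrom = config.chrom_length // config.gene_spacing
    genes = []
    for i in range(config.n_genes):
        chrom = f"chr{i // per_chrom + 1}"
        start = (i % per_chrom) * config.gene_spacing
        genes.append(
            GeneModel(f"G{i:05d}", chrom, start, start + config.gene_length)
        )
    return genes


class _VariantFactory:
    """Allocates distinct positions within each gene's footprint."""

    def __init__(self, gene_models: Sequence[GeneModel]):
        self.by_gene = {g.gene: g for g in gene_models}
        self.counters: dict[str, int] = {}

    def next_key(self, gene: str, ref: str = "A", alt: str = "G") -> VariantKey:
        model = self.by_gene[gene]
        offset = self.counters.get(gene, 0)
        self.counters[gene] = offset + 1
        pos = model.start + 1 + offset  # 1-based
        if pos > model.end:
            raise ValueError(f"gene {gene} footprint exhausted")
        return VariantKey(model.chrom, pos, ref, alt)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort with planted ground truth (deterministic in
    ``config.seed``)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    manifest = CohortManifest(list(_MANIFEST_ENTRIES))
    wes = list(_WES_SAMPLES)
    wes_by_group = {g: [s for s in wes if manifest.group_of(s) == g] for g in ("S", "L")}
    gene_models = _gene_layout(config)
    gene_names = [g.gene for g in gene_models]
    factory = _VariantFactory(gene_models)

    n_shared = config.n_mutated_s + config.n_mutated_l - config.n_mutated_union
    n_s_only = config.n_mutated_union - config.n_mutated_l
    n_l_only = config.n_mutated_union - config.n_mutated_s

    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = gene_names[cursor:cursor + n]
        cursor += n
        return out

    hyper_s_genes = take(config.n_hyper["S"])
    hyper_l_genes = hyper_s_genes[: config.n_hyper["L"]]
    universal_genes = take(config.n_universal_variants)
    deg_sl_only = take(config.n_deg_sl_only)
    deg_triple = take(config.n_deg_triple)
    deg_sm_ml = take(config.n_deg_sm_ml)
    shared_background = take(
        n_shared - config.n_hyper["S"] - config.n_universal_variants
        - config.n_deg_total
    )
    recurrent_s = take(config.n_recurrent["S"])
    excl_var_s_genes = take(config.n_exclusive_shared_variants["S"])
    s_only_background = take(
        n_s_only - config.n_recurrent["S"] - config.n_exclusive_shared_variants["S"]
    )
    recurrent_l = take(config.n_recurrent["L"])
    excl_var_l_genes = take(config.n_exclusive_shared_variants["L"])
    l_only_background = take(
        n_l_only - config.n_recurrent["L"] - config.n_exclusive_shared_variants["L"]
    )
    # remaining genes are never mutated (expression-only universe)

    shared_genes = (hyper_s_genes + universal_genes + deg_sl_only + deg_triple
                    + deg_sm_ml + shared_background)
    s_genes = shared_genes + recurrent_s + excl_var_s_genes + s_only_background
    l_genes = shared_genes + recurrent_l + excl_var_l_genes + l_only_background

    # --- variant planting ------------------------------------------------
    # rows: (sample_id, key, gene, force_coding)
    rows: dict[str, list] = {"S": [], "L": []}

    def plant(group: str, gene: str, sample: str, key: VariantKey,
              force_coding: bool = False) -> None:
        rows[group].append((sample, key, gene, force_coding))

    def random_sample(group: str) -> str:
        pool = wes_by_group[group]
        return pool[rng.integers(0, len(pool))]

    # hypermutator genes: descending distinct counts from hyper_top
    for i, gene in enumerate(hyper_s_genes):
        for _ in range(config.hyper_top["S"] - i):
            plant("S", gene, random_sample("S"), factory.next_key(gene))
        if gene in hyper_l_genes:
            j = hyper_l_genes.index(gene)
            for _ in range(config.hyper_top["L"] - j):
                plant("L", gene, random_sample("L"), factory.next_key(gene))
        else:
            plant("L", gene, random_sample("L"), factory.next_key(gene))

    # cohort-universal variant keys: one key in every WES sample
    universal_keys: set[VariantKey] = set()
    for gene in universal_genes:
        key = factory.next_key(gene)
        universal_keys.add(key)
        for g in ("S", "L"):
            for sample in wes_by_group[g]:
                plant(g, gene, sample, key, force_coding=True)

    # ordinary shared genes: one variant in each group
    for gene in deg_sl_only + deg_triple + deg_sm_ml + shared_background:
        plant("S", gene, random_sample("S"), factory.next_key(gene))
        plant("L", gene, random_sample("L"), factory.next_key(gene))

    # recurrent group genes: one variant per sample plus one extra, all
    # distinct, so no single key is shared by the whole group
    recurrent_truth: dict[str, dict[str, int]] = {"S": {}, "L": {}}
    for group, genes in (("S", recurrent_s), ("L", recurrent_l)):
        for gene in genes:
            for sample in wes_by_group[group]:
                plant(group, gene, sample, factory.next_key(gene))
            for _ in range(config.recurrent_distinct - len(wes_by_group[group])):
                plant(group, gene, random_sample(group), factory.next_key(gene))
            recurrent_truth[group][gene] = config.recurrent_distinct

    # group-exclusive universally shared variants: one key in every
    # sample of the group, absent from the other group
    excl_keys: dict[str, set[VariantKey]] = {"S": set(), "L": set()}
    for group, genes in (("S", excl_var_s_genes), ("L", excl_var_l_genes)):
        for i, gene in enumerate(genes):
            if i == 0 and len(genes) > 1:
                key = factory.next_key(gene, ref="AT", alt="A")  # one deletion
            else:
                key = factory.next_key(gene)
            excl_keys[group].add(key)
            for sample in wes_by_group[group]:
                plant(group, gene, sample, key, force_coding=True)

    # group-exclusive background genes: one variant in one sample
    for gene in s_only_background:
        plant("S", gene, random_sample("S"), factory.next_key(gene))
    for gene in l_only_background:
        plant("L", gene, random_sample("L"), factory.next_key(gene))

    # background occurrence padding to exact per-group totals, confined
    # to genes mutated in both groups (cannot perturb set structures);
    # hypermutator genes are excluded to keep their counts as planted
    padding_genes = (universal_genes + deg_sl_only + deg_triple + deg_sm_ml
                     + shared_background)
    for group in ("S", "L"):
        planted = len(rows[group])
        remaining = config.total_occurrences[group] - planted
        if remaining < 0:
            raise ValueError(
                f"total_occurrences[{group}] = {config.total_occurrences[group]} "
                f"below the {planted} occurrences the planted structures require"
            )
        if remaining and not padding_genes:
            raise ValueError("no shared genes available for occurrence padding")
        if remaining:
            alloc = rng.multinomial(
                remaining, np.full(len(padding_genes), 1.0 / len(padding_genes))
            )
            pool = wes_by_group[group]
            for gene, k in zip(padding_genes, alloc):
                if not k:
                    continue
                samples = rng.integers(0, len(pool), size=k)
                for s in samples:
                    plant(group, gene, pool[s], factory.next_key(gene))

    # --- annotation flags: exact coding/deleterious totals per group -----
    records: list[VariantRecord] = []
    burden_truth: dict[str, dict[str, int]] = {}
    for group in ("S", "L"):
        group_rows = rows[group]
        n = len(group_rows)
        forced = np.array([r[3] for r in group_rows], dtype=bool)
        n_forced = int(forced.sum())
        if config.n_coding[group] < n_forced:
            raise ValueError(
                f"n_coding[{group}] below the {n_forced} records planted as coding"
            )
        coding = forced.copy()
        free = np.flatnonzero(~forced)
        extra = rng.permutation(free)[: config.n_coding[group] - n_forced]
        coding[extra] = True
        deleterious = np.zeros(n, dtype=bool)
        coding_idx = rng.permutation(np.flatnonzero(coding))
        deleterious[coding_idx[: config.n_deleterious[group]]] = True
        for (sample, key, gene, _), is_c, is_d in zip(group_rows, coding, deleterious):
            if key.ref != "A" or len(key.alt) != 1 or len(key.ref) != 1:
                vclass = "deletion" if len(key.ref) > len(key.alt) else "insertion"
                conseq = "frameshift" if is_c else "noncoding"
            else:
                vclass = "SNV"
                conseq = "missense" if is_c else "noncoding"
            records.append(
                VariantRecord(
                    sample_id=sample,
                    chrom=key.chrom,
                    pos=key.pos,
                    ref=key.ref,
                    alt=key.alt,
                    gene=gene,
                    variant_class=vclass,
                    zygosity="heterozygous",
                    consequence=conseq,
                    is_coding=bool(is_c),
                    is_deleterious=bool(is_d),
                    alt_allele_fraction=None,
                )
            )
        burden_truth[group] = {
            "n_total": n,
            "n_coding": int(coding.sum()),
            "n_deleterious": int(deleterious.sum()),
        }

    # --- expression -------------------------------------------------------
    samples = manifest.sample_ids
    group_of = {s: manifest.group_of(s) for s in samples}
    lo, hi = config.baseline_range
    baseline = rng.uniform(lo, hi, size=config.n_genes)
    log_expr = np.tile(baseline[:, None], (1, len(samples)))
    gene_index = {g: i for i, g in enumerate(gene_names)}
    col = {s: j for j, s in enumerate(samples)}

    def set_group(gene: str, group: str, value_shift: float) -> None:
        i = gene_index[gene]
        for s in samples:
            if group_of[s] == group:
                log_expr[i, col[s]] = baseline[i] + value_shift

    # SL-only genes: S and L differ cleanly while the M group sits at the
    # midpoint with a fixed high within-group spread, so neither S-vs-M
    # nor M-vs-L reaches significance.  The spread pattern is
    # deterministic: random draws could land arbitrarily close together
    # and produce a spuriously tiny Welch standard error.
    m_samples = [s for s in samples if group_of[s] == "M"]
    m_offsets = (
        np.linspace(-1.0, 1.0, len(m_samples)) * config.m_noise_sd
        if len(m_samples) > 1
        else np.zeros(len(m_samples))
    )
    for gene in deg_sl_only:
        set_group(gene, "S", config.deg_delta)
        set_group(gene, "L", 0.0)
        i = gene_index[gene]
        for s, off in zip(m_samples, m_offsets):
            log_expr[i, col[s]] = baseline[i] + config.deg_delta / 2.0 + off
    for gene in deg_triple:
        set_group(gene, "S", 1.0)
        set_group(gene, "L", 0.0)
        set_group(gene, "M", config.m_shift)
    for gene in deg_sm_ml:
        set_group(gene, "M", config.m_shift)

    if config.expression_noise_sd > 0:
        log_expr = log_expr + rng.normal(
            0.0, config.expression_noise_sd, size=log_expr.shape
        )
    log_expr = np.clip(log_expr, 0.0, None)
    fpkm = np.power(2.0, log_expr) - 1.0
    expression = ExpressionMatrix(
        pd.DataFrame(fpkm, index=pd.Index(gene_names, name="gene"), columns=samples)
    )

    # --- coverage ---------------------------------------------------------
    n_bins = config.chrom_length // config.bin_size
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    bin_frame = pd.DataFrame(
        {
            "chrom": np.repeat(chroms, n_bins),
            "start": np.tile(np.arange(n_bins) * config.bin_size, len(chroms)),
            "end": np.tile((np.arange(n_bins) + 1) * config.bin_size, len(chroms)),
        }
    )

    def fold_vector(group: Optional[str]) -> np.ndarray:
        fold = np.ones(len(bin_frame))
        for region in config.cnv_regions:
            if group is not None and group not in region.groups:
                continue
            lo_i = region.chrom_index * n_bins + region.bin_start
            hi_i = region.chrom_index * n_bins + region.bin_end
            fold[lo_i:hi_i] = region.fold
        return fold

    def make_track(sample_id: str, fold: np.ndarray) -> CoverageTrack:
        lam = config.depth * fold
        counts = rng.poisson(lam) if config.poisson_coverage else np.round(lam)
        return CoverageTrack(
            sample_id, bin_frame.assign(count=counts.astype(int))
        )

    coverage = {
        s: make_track(s, fold_vector(manifest.group_of(s))) for s in wes
    }
    normal = make_track("normal", np.ones(len(bin_frame)))

    chrom_of = {i: chroms[i] for i in range(config.n_chromosomes)}
    truth = GroundTruth(
        mutated_genes={"S": set(s_genes), "L": set(l_genes)},
        union_genes=set(s_genes) | set(l_genes),
        exclusive_genes={
            "S": set(s_genes) - set(l_genes),
            "L": set(l_genes) - set(s_genes),
        },
        hypermutated={"S": set(hyper_s_genes), "L": set(hyper_l_genes)},
        recurrent_genes=recurrent_truth,
        exclusive_shared_variants=excl_keys,
        universal_variants=universal_keys,
        burden_totals=burden_truth,
        deg_sl_only=set(deg_sl_only),
        deg_triple=set(deg_triple),
        deg_sm_ml=set(deg_sm_ml),
        cnv_regions=[
            (
                chrom_of[r.chrom_index],
                r.bin_start * config.bin_size,
                r.bin_end * config.bin_size,
                r.fold,
                r.groups,
            )
            for r in config.cnv_regions
        ],
    )
    return SyntheticCohort(
        config=config,
        manifest=manifest,
        wes_samples=wes,
        records=records,
        expression=expression,
        coverage=coverage,
        normal=normal,
        gene_models=gene_models,
        truth=truth,
    )


def paper_scale_config(seed: int = 0) -> CohortConfig:
    """Preset planting the published counts where set-exact recovery is
    possible; occurrence totals are exact by construction.

    Note the published exclusive-gene counts (2914 S / 1426 L) are
    arithmetically incompatible with the published group sets
    (12714 / 11126) and union (15610); the group sets and union are
    planted, and the exclusive counts follow from them (4484 / 2896).
    """
    return CohortConfig(
        seed=seed,
        n_genes=16_610,
        n_mutated_s=12_714,
        n_mutated_l=11_126,
        n_mutated_union=15_610,
        n_recurrent={"S": 46, "L": 5},
        recurrent_distinct=5,
        n_hyper={"S": 35, "L": 9},
        hyper_top={"S": 105, "L": 75},
        n_exclusive_shared_variants={"S": 17, "L": 2},
        n_universal_variants=5,
        total_occurrences={"S": 76_170, "L": 45_903},
        n_coding={"S": 53_319, "L": 33_050},
        n_deleterious={"S": 39_609, "L": 24_328},
        n_deg_sl_only=112,
        n_deg_triple=13,
        n_deg_sm_ml=33,
    )


def small_config(seed: int = 0) -> CohortConfig:
    """Desk-scale preset with the same structure (fast tests)."""
    return CohortConfig(seed=seed)
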