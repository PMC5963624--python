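"""Per-group mutational burden accounting and per-gene burden matrices.

Two counting conventions coexist deliberately.  Cohort-level burden
totals are per-occurrence (each sample's record counts once), which is
how the headline totals of a multi-sample exome screen are usually
quoted.  Per-gene group counts are distinct variant keys per group, so
that a variant shared by every sample of a group is one event of the
gene rather than four of the cohort; this is the convention under
which "the most mutated gene has 105 variants in the S group" is a
property of the gene, and it is the default for hypermutation
flagging.  Both are computed and reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cohort import CohortManifest, VariantRecord, records_to_frame

HYPERMUTATION_THRESHOLD = 50  # "more than 50 variants per gene", strict


@dataclass(frozen=True)
class BurdenSummary:
    """Per-occurrence variant totals for one RFS group."""

    group: str
    n_total: int
    n_coding: int
    n_deleterious: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_deleterious <= self.n_coding <= self.n_total):
            raise ValueError(
                f"inconsistent burden counts for group {self.group}: "
                f"{self.n_deleterious} <= {self.n_coding} <= {self.n_total} violated"
            )

    @property
    def frac_coding_of_total(self) -> float:
        return self.n_coding / self.n_total if self.n_total else 0.0

    @property
    def frac_deleterious_of_total(self) -> float:
        return self.n_deleterious / self.n_total if self.n_total else 0.0

    @property
    def frac_deleterious_of_coding(self) -> float:
        return self.n_deleterious / self.n_coding if self.n_coding else 0.0


@dataclass
class GeneBurdenMatrix:
    """Gene x sample distinct-variant counts with per-group summaries.

    ``per_sample``      gene x sample, distinct keys of that gene in that sample
    ``per_group``       gene x group, distinct keys across the group's samples
    ``per_group_occurrence``  gene x group, occurrence (record) counts
    """

    per_sample: pd.DataFrame
    per_group: pd.DataFrame
    per_group_occurrence: pd.DataFrame
    manifest: CohortManifest

    @property
    def genes(self) -> list[str]:
        return list(self.per_sample.index)

    @property
    def groups(self) -> list[str]:
        return list(self.per_group.columns)


def _check_samples(frame: pd.DataFrame, manifest: CohortManifest) -> None:
    known = set(manifest.sample_ids)
    unknown = set(frame["sample_id"].unique()) - known
    if unknown:
        raise ValueError(f"records for sample(s) not in manifest: {sorted(unknown)}")


def summarize_burden(
    records: Sequence[VariantRecord], manifest: CohortManifest
) -> list[BurdenSummary]:
    """Per-occurrence totals (total / coding / deleterious) per group."""
    frame = records_to_frame(records)
    if len(frame):
        _check_samples(frame, manifest)
        group_map = {sid: manifest.group_of(sid) for sid in frame["sample_id"].unique()}
        frame = frame.assign(group=frame["sample_id"].map(group_map))
    summaries = []
    for group in manifest.groups:
        sub = frame[frame["group"] == group] if len(frame) else frame
        summaries.append(
            BurdenSummary(
                group=group,
                n_total=int(len(sub)),
                n_coding=int(sub["is_coding"].sum()) if len(sub) else 0,
                n_deleterious=int(sub["is_deleterious"].sum()) if len(sub) else 0,
            )
        )
    return summaries


def build_gene_burden_matrix(
    records: Sequence[VariantRecord], manifest: CohortManifest
) -> GeneBurdenMatrix:
    """Distinct-variant counts per (gene, sample) and per (gene, group).

    Records without a gene annotation (gene == ".") are excluded.
    """
    frame = records_to_frame(records)
    if len(frame):
        _check_samples(frame, manifest)
        frame = frame[frame["gene"] != "."]
    samples = manifest.sample_ids
    groups = manifest.groups
    if not len(frame):
        empty = pd.DataFrame(index=pd.Index([], name="gene"))
        return GeneBurdenMatrix(
            per_sample=empty.reindex(columns=samples, fill_value=0),
            per_group=empty.reindex(columns=groups, fill_value=0),
            per_group_occurrence=empty.reindex(columns=groups, fill_value=0),
            manifest=manifest,
        )
    group_map = {sid: manifest.group_of(sid) for sid in samples}
    frame = frame.assign(group=frame["sample_id"].map(group_map))

    per_sample = (
        frame.groupby(["gene", "sample_id"])["key"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(columns=samples, fill_value=0)
    )
    per_group = (
        frame.groupby(["gene", "group"])["key"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(columns=groups, fill_value=0)
        .reindex(per_sample.index, fill_value=0)
    )
    per_group_occ = (
        frame.groupby(["gene", "group"])["key"]
        .size()
        .unstack(fill_value=0)
        .reindex(columns=groups, fill_value=0)
        .reindex(per_sample.index, fill_value=0)
    )
    per_sample.index.name = "gene"
    return GeneBurdenMatrix(
        per_sample=per_sample.astype(int),
        per_group=per_group.astype(int),
        per_group_occurrence=per_group_occ.astype(int),
        manifest=manifest,
    )


def mutated_gene_sets(
    matrix: GeneBurdenMatrix,
) -> tuple[dict[str, set[str]], set[str]]:
    """Genes carrying at least one variant per group, plus their union."""
    sets: dict[str, set[str]] = {}
    for group in matrix.groups:
        col = matrix.per_group[group]
        sets[group] = set(col.index[col > 0])
    union: set[str] = set().union(*sets.values()) if sets else set()
    return sets, union


def flag_hypermutated(
    matrix: GeneBurdenMatrix, threshold: int = HYPERMUTATION_THRESHOLD
) -> dict[str, set[str]]:
    """Genes with MORE THAN ``threshold`` distinct variants in a group.

    The comparison is strict: a gene with exactly ``threshold`` group
    variants is not flagged.
    """
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    flags: dict[str, set[str]] = {}
    for group in matrix.groups:
        col = matrix.per_group[group]
        flags[group] = set(col.index[col > threshold])
    return flags


def write_burden_summary(
    summaries: Iterable[BurdenSummary], path: str | Path
) -> None:
    rows = [
        {
            "group": s.group,
            "n_total": s.n_total,
            "n_coding": s.n_coding,
            "n_deleterious": s.n_deleterious,
            "frac_coding_of_total": s.frac_coding_of_total,
            "frac_deleterious_of_total": s.frac_deleterious_of_total,
            "frac_deleterious_of_coding": s.frac_deleterious_of_coding,
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_gene_burden(
    matrix: GeneBurdenMatrix,
    hyper_flags: dict[str, set[str]],
    path: str | Path,
) -> None:
    out = matrix.per_sample.copy()
    for group in matrix.groups:
        out[f"distinct_{group}"] = matrix.per_group[group]
        out[f"occurrences_{group}"] = matrix.per_group_occurrence[group]
        out[f"hypermutated_{group}"] = [
            g in hyper_flags.get(group, set()) for g in out.index
        ]
    out.to_csv(path, sep="\t")
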