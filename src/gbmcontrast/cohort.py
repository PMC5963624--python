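"""Domain types for the glioblastoma cohort-contrast pipeline.

The cohort under study is a set of IDH1 wild-type primary glioblastoma
(GBM) tumors grouped by recurrence-free survival (RFS) after first
surgery: Short (S, < 6 months), Medium (M, 16-23 months) and Long
(L, > 25 months).  Downstream modules consume only the types defined
here: per-sample somatic variant calls with functional annotations, a
sample-to-group manifest, a gene x sample FPKM expression matrix,
windowed read-count coverage tracks, and a BED-style gene model.

Coordinate conventions: variants are 1-based (VCF); intervals are
0-based half-open (BED).  Conversions happen only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

GROUPS = ("S", "M", "L")

VARIANT_CLASSES = ("SNV", "insertion", "deletion")
ZYGOSITIES = ("heterozygous", "homozygous")
CONSEQUENCES = (
    "missense",
    "stop_gained",
    "synonymous",
    "frameshift",
    "inframe_indel",
    "splice",
    "noncoding",
    "other",
)


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a variant: (chrom, pos, ref, alt).

    Two records in different samples describe the same variant iff
    their keys are equal.  Identity is deliberately sample-, zygosity-
    and annotation-independent.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def from_string(cls, s: str) -> "VariantKey":
        chrom, pos, ref, alt = s.split(":")
        return cls(chrom, int(pos), ref, alt)


def infer_variant_class(ref: str, alt: str) -> str:
    """SNV iff both alleles are single bases; otherwise indel by length."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


@dataclass(frozen=True)
class VariantRecord:
    """One called variant in one sample, with functional annotations.

    ``is_deleterious`` is an input annotation (the upstream caller's
    pathogenicity flag), never recomputed here; by convention
    deleterious variants are a subset of coding variants.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    gene: str  # "." when the call carries no gene annotation
    variant_class: str
    zygosity: str
    consequence: str
    is_coding: bool
    is_deleterious: bool
    alt_allele_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if infer_variant_class(self.ref, self.alt) != self.variant_class:
            raise ValueError(
                f"variant_class {self.variant_class!r} inconsistent with "
                f"alleles {self.ref}>{self.alt}"
            )
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.is_deleterious and not self.is_coding:
            raise ValueError("deleterious variants must be coding")
        if self.alt_allele_fraction is not None and not (
            0.0 <= self.alt_allele_fraction <= 1.0
        ):
            raise ValueError("alt_allele_fraction outside [0, 1]")

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)


_RECORD_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "variant_class",
    "zygosity",
    "consequence",
    "is_coding",
    "is_deleterious",
    "alt_allele_fraction",
]


def records_to_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Tabular view of a record list for vectorized group-by operations.

    Adds a ``key`` column with the string form of each VariantKey.
    """
    rows = [
        (
            r.sample_id,
            r.chrom,
            r.pos,
            r.ref,
            r.alt,
            r.gene,
            r.variant_class,
            r.zygosity,
            r.consequence,
            r.is_coding,
            r.is_deleterious,
            np.nan if r.alt_allele_fraction is None else r.alt_allele_fraction,
        )
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=_RECORD_COLUMNS)
    if len(frame):
        frame["key"] = (
            frame["chrom"].astype(str)
            + ":"
            + frame["pos"].astype(str)
            + ":"
            + frame["ref"]
            + ":"
            + frame["alt"]
        )
    else:
        frame["key"] = pd.Series(dtype=str)
    return frame


@dataclass
class CohortManifest:
    """Sample-to-group mapping with recurrence-free survival in months.

    Groups are ordered S < M < L on their RFS ranges; the constructor
    enforces unique sample ids and non-overlapping group RFS ranges.
    """

    entries: list[tuple[str, str, int]]  # (sample_id, group, rfs_months)

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_id(s): {dup}")
        for sid, grp, rfs in self.entries:
            if grp not in GROUPS:
                raise ValueError(f"group {grp!r} for sample {sid!r} not in {GROUPS}")
            if rfs <= 0:
                raise ValueError(f"rfs_months must be positive for sample {sid!r}")
        ranges = {
            g: [rfs for _, grp, rfs in self.entries if grp == g] for g in GROUPS
        }
        order = [g for g in GROUPS if ranges[g]]
        for a, b in zip(order, order[1:]):
            if max(ranges[a]) >= min(ranges[b]):
                raise ValueError(
                    f"RFS ranges of groups {a} and {b} overlap; expected "
                    "S < M < L ordering"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def groups(self) -> list[str]:
        """Groups present, in canonical S, M, L order."""
        present = {e[1] for e in self.entries}
        return [g for g in GROUPS if g in present]

    def group_of(self, sample_id: str) -> str:
        for sid, grp, _ in self.entries:
            if sid == sample_id:
                return grp
        raise KeyError(f"unknown sample_id {sample_id!r}")

    def samples_in(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise KeyError(f"unknown group {group!r}")
        return [sid for sid, grp, _ in self.entries if grp == group]

    def subset(self, sample_ids: Iterable[str]) -> "CohortManifest":
        """Manifest restricted to the given samples (e.g. the WES subset)."""
        keep = set(sample_ids)
        unknown = keep - set(self.sample_ids)
        if unknown:
            raise KeyError(f"unknown sample_id(s): {sorted(unknown)}")
        return CohortManifest([e for e in self.entries if e[0] in keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["sample_id", "group", "rfs_months"]
        )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of FPKM values (non-negative reals)."""

    values: pd.DataFrame  # index = gene symbols, columns = sample ids

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("NaN FPKM values")
        if (arr < 0).any():
            raise ValueError("negative FPKM values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CoverageTrack:
    """Windowed read counts for one sample.

    Bins are 0-based half-open, non-overlapping and sorted within each
    chromosome; counts are non-negative integers.
    """

    sample_id: str
    bins: pd.DataFrame  # columns chrom, start, end, count

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "count"]
        if list(self.bins.columns) != required:
            self.bins = self.bins[required]
        if (self.bins["end"] <= self.bins["start"]).any():
            raise ValueError("coverage bin with end <= start")
        if (self.bins["count"] < 0).any():
            raise ValueError("negative read count")
        for chrom, sub in self.bins.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if not (starts[1:] >= ends[:-1]).all():
                raise ValueError(
                    f"overlapping or unsorted coverage bins on {chrom}"
                )

    def same_binning(self, other: "CoverageTrack") -> bool:
        a = self.bins[["chrom", "start", "end"]].reset_index(drop=True)
        b = other.bins[["chrom", "start", "end"]].reset_index(drop=True)
        return a.equals(b)

    @property
    def total(self) -> int:
        return int(self.bins["count"].sum())

    def __len__(self) -> int:
        return len(self.bins)


@dataclass(frozen=True)
class GeneModel:
    """One genomic interval per gene (longest transcript footprint), BED
    convention (0-based half-open)."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene}: end <= start")
        if self.start < 0:
            raise ValueError(f"gene {self.gene}: negative start")
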