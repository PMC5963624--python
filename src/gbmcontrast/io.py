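"""Readers and writers for the pipeline's file dialects.

Variant calls are accepted either as VCF 4.x (per-sample or
multi-sample, annotations in INFO fields named by an annotation spec)
or as a tab-separated dialect whose columns are exactly the
VariantRecord fields.  Manifests, expression matrices, coverage tracks
and gene models are plain TSV/BED.  All writers emit UTF-8,
tab-delimited text with a single header line (BED has none).

Readers never silently drop rows: malformed lines raise with the line
number, and recoverable oddities (an unknown consequence term) are
mapped to ``other`` with a logged warning.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .cohort import (
    CONSEQUENCES,
    CohortManifest,
    CoverageTrack,
    ExpressionMatrix,
    GeneModel,
    VariantRecord,
    infer_variant_class,
)

logger = logging.getLogger(__name__)

#: Default INFO-field names for VCF annotations; override via
#: ``annotation_spec`` in :func:`read_variants`.
DEFAULT_ANNOTATION_SPEC = {
    "gene": "GENE",
    "consequence": "CONSEQUENCE",
    "coding": "CODING",
    "deleterious": "DELETERIOUS",
}

_VARIANT_COLUMNS = [
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


def _coerce_consequence(term: str, context: str) -> str:
    term = str(term)
    if term not in CONSEQUENCES:
        logger.warning("unknown consequence term %r (%s); mapped to 'other'", term, context)
        return "other"
    return term


def _parse_bool(value: object) -> bool:
    s = str(value).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise ValueError(f"cannot parse boolean value {value!r}")


def read_variants(
    path: str | Path,
    format: str = "tsv",
    annotation_spec: Optional[Mapping[str, str]] = None,
) -> list[VariantRecord]:
    """Read variant calls from a TSV dialect file or a VCF.

    For VCF input, ``annotation_spec`` maps the logical annotation
    names ``gene``, ``consequence``, ``coding`` and ``deleterious`` to
    the INFO fields that carry them.  Records whose gene annotation is
    missing are kept with gene ``"."`` (they are excluded later from
    gene-level operations).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_variants_tsv(path)
    if format == "vcf":
        return _read_variants_vcf(path, annotation_spec or DEFAULT_ANNOTATION_SPEC)
    raise ValueError(f"unknown variant format {format!r}")


def _read_variants_tsv(path: Path) -> list[VariantRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _VARIANT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing variant columns {missing}")
    records: list[VariantRecord] = []
    for lineno, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            aaf = getattr(row, "alt_allele_fraction")
            records.append(
                VariantRecord(
                    sample_id=row.sample_id,
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    gene=row.gene if row.gene else ".",
                    variant_class=row.variant_class,
                    zygosity=row.zygosity,
                    consequence=_coerce_consequence(
                        row.consequence, f"{path}:{lineno}"
                    ),
                    is_coding=_parse_bool(row.is_coding),
                    is_deleterious=_parse_bool(row.is_deleterious),
                    alt_allele_fraction=float(aaf) if aaf not in ("", ".") else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return records


def _info_scalar(info: Mapping, field: str):
    value = info.get(field)
    if isinstance(value, tuple):
        value = value[0] if value else None
    return value


def _read_variants_vcf(path: Path, spec: Mapping[str, str]) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        for rec in vcf:
            gene = _info_scalar(rec.info, spec["gene"])
            gene = str(gene) if gene not in (None, "") else "."
            conseq = _info_scalar(rec.info, spec["consequence"])
            conseq = _coerce_consequence(
                conseq if conseq is not None else "other",
                f"{path}:{rec.chrom}:{rec.pos}",
            )
            coding = bool(rec.info.get(spec["coding"], False))
            delet = bool(rec.info.get(spec["deleterious"], False))
            for alt in rec.alts or ():
                for sample in vcf_samples:
                    gt = rec.samples[sample].get("GT")
                    if gt is None or not any(a and a > 0 for a in gt if a is not None):
                        continue
                    alleles = [a for a in gt if a is not None]
                    zygosity = (
                        "homozygous"
                        if len(alleles) > 1 and all(a > 0 for a in alleles)
                        else "heterozygous"
                    )
                    af = rec.samples[sample].get("AF")
                    if isinstance(af, tuple):
                        af = af[0] if af else None
                    records.append(
                        VariantRecord(
                            sample_id=sample,
                            chrom=str(rec.chrom),
                            pos=int(rec.pos),
                            ref=str(rec.ref),
                            alt=str(alt),
                            gene=gene,
                            variant_class=infer_variant_class(str(rec.ref), str(alt)),
                            zygosity=zygosity,
                            consequence=conseq,
                            is_coding=coding or delet,
                            is_deleterious=delet,
                            alt_allele_fraction=float(af) if af is not None else None,
                        )
                    )
    return records


def write_variants(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records in the TSV variant dialect (one header line)."""
    rows = []
    for r in records:
        rows.append(
            [
                r.sample_id,
                r.chrom,
                r.pos,
                r.ref,
                r.alt,
                r.gene,
                r.variant_class,
                r.zygosity,
                r.consequence,
                str(r.is_coding).lower(),
                str(r.is_deleterious).lower(),
                "" if r.alt_allele_fraction is None else repr(r.alt_allele_fraction),
            ]
        )
    frame = pd.DataFrame(rows, columns=_VARIANT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a sample_id / group / rfs_months TSV manifest."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    required = ["sample_id", "group", "rfs_months"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing manifest columns {missing}")
    entries = [
        (str(r.sample_id), str(r.group), int(r.rfs_months))
        for r in frame.itertuples(index=False)
    ]
    return CohortManifest(entries)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample FPKM matrix; first column is the gene symbol."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.index.name = "gene"
    return ExpressionMatrix(frame.astype(float))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_coverage(path: str | Path, sample_id: Optional[str] = None) -> CoverageTrack:
    """Read a windowed coverage TSV (chrom, start, end, count).

    ``sample_id`` defaults to the file stem.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "start", "end", "count"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing coverage columns {missing}")
    frame = frame[required].astype(
        {"start": int, "end": int, "count": int}, errors="raise"
    )
    return CoverageTrack(sample_id or path.stem, frame)


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    track.bins.to_csv(path, sep="\t", index=False)


def read_gene_model(path: str | Path) -> list[GeneModel]:
    """Read a BED4 gene model: chrom, start, end, gene (no header)."""
    genes: list[GeneModel] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected BED4")
            try:
                genes.append(
                    GeneModel(
                        gene=parts[3],
                        chrom=parts[0],
                        start=int(parts[1]),
                        end=int(parts[2]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    seen: set[str] = set()
    for g in genes:
        if g.gene in seen:
            raise ValueError(f"{path}: duplicate gene interval for {g.gene}")
        seen.add(g.gene)
    return genes


def write_gene_model(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene}\n")
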