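"""Windowed log2-ratio copy-number contrast with SD-banded cut-offs.

Coverage tracks (read counts per fixed genomic bin) are compared as
log2 ratios after library-size normalization: every track is scaled so
its genome-wide total equals a fixed reference depth per bin, which
makes the ratio exactly invariant to multiplying any input track by a
constant.  A pseudocount guards empty bins.

Aberrant segments are called with a cut-off c and an SD band b (the
published parameterization "c ± b SD", c = 1.0 for tumor vs normal
blood and c = 0.8 for the Short-vs-Long group contrast, b = 0.5): a
bin joins an amplified (deleted) run when its log2 ratio is at least
c - b (at most -(c - b)); maximal same-sign runs of at least
``min_bins`` bins are retained when their within-run standard
deviation does not exceed b (a stability filter against noisy spikes).
The band makes calls robust when the underlying fold change sits
exactly at the cut-off — a clean 2x gain has an expected log2 ratio of
1.0, i.e. on the knife edge of the tumor-vs-normal threshold.
Remaining territory is reported as neutral segments, so segments tile
the binned genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortManifest, CoverageTrack, ExpressionMatrix, GeneModel

#: Per-bin depth every track is scaled to before forming ratios.
REFERENCE_DEPTH = 100.0


@dataclass
class CnvTrack:
    """Per-bin log2 ratios over the shared binning of its inputs."""

    bins: pd.DataFrame  # columns chrom, start, end, log2_ratio
    test_ids: tuple[str, ...]
    control_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.bins)


@dataclass(frozen=True)
class CnvSegment:
    chrom: str
    start: int
    end: int
    state: str  # amplified / deleted / neutral
    mean_log2: float
    sd_log2: float
    n_bins: int


def _as_tracks(obj) -> list[CoverageTrack]:
    if isinstance(obj, CoverageTrack):
        return [obj]
    tracks = list(obj)
    if not tracks:
        raise ValueError("empty track group")
    return tracks


def _check_binning(tracks: Sequence[CoverageTrack]) -> pd.DataFrame:
    ref = tracks[0].bins[["chrom", "start", "end"]].reset_index(drop=True)
    for t in tracks[1:]:
        if not tracks[0].same_binning(t):
            raise ValueError(
                f"binning mismatch between tracks {tracks[0].sample_id!r} "
                f"and {t.sample_id!r}"
            )
    return ref


def _normalized_mean(tracks: Sequence[CoverageTrack]) -> np.ndarray:
    """Mean over member tracks of counts scaled to REFERENCE_DEPTH/bin.

    Dividing by the total before rescaling makes the result bit-exactly
    invariant to multiplying a track's integer counts by a constant.
    """
    n_bins = len(tracks[0])
    scaled = []
    for t in tracks:
        counts = t.bins["count"].to_numpy(dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError(f"track {t.sample_id!r} has zero total count")
        scaled.append((counts / total) * (REFERENCE_DEPTH * n_bins))
    return np.mean(scaled, axis=0)


def log2_ratio_track(
    test, control, pseudocount: float = 0.5
) -> CnvTrack:
    """Per-bin log2 of normalized test over control coverage.

    ``test`` and ``control`` are a CoverageTrack or a sequence of
    tracks sharing one binning; for groups the per-bin mean of the
    normalized member tracks is used on each side.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    test_tracks = _as_tracks(test)
    control_tracks = _as_tracks(control)
    ref = _check_binning(test_tracks + control_tracks)
    t = _normalized_mean(test_tracks)
    c = _normalized_mean(control_tracks)
    # difference of logs, not log of quotient: keeps group-swap
    # antisymmetry bit-exact
    ratio = np.log2(t + pseudocount) - np.log2(c + pseudocount)
    # median-center so the modal (diploid) copy state sits at zero:
    # otherwise total-count scaling shifts the baseline down by the mass
    # of any amplified territory
    ratio = ratio - np.median(ratio)
    bins = ref.assign(log2_ratio=ratio)
    return CnvTrack(
        bins=bins,
        test_ids=tuple(x.sample_id for x in test_tracks),
        control_ids=tuple(x.sample_id for x in control_tracks),
    )


def group_contrast_track(
    tracks_g1: Sequence[CoverageTrack],
    tracks_g2: Sequence[CoverageTrack],
    pseudocount: float = 0.5,
) -> CnvTrack:
    """Group-vs-group log2 ratio; positive means higher copy in group 1.

    Exactly antisymmetric under swapping the two groups.
    """
    return log2_ratio_track(tracks_g1, tracks_g2, pseudocount=pseudocount)


def call_segments(
    track: CnvTrack,
    cutoff: float,
    sd_band: float = 0.5,
    min_bins: int = 5,
) -> list[CnvSegment]:
    """Threshold a log2-ratio track into amplified/deleted/neutral
    segments tiling the binned territory (see module docstring for the
    cut-off ± SD-band rule)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if min_bins < 1:
        raise ValueError("min_bins must be >= 1")
    entry = cutoff - sd_band
    if entry <= 0:
        raise ValueError(
            f"sd_band {sd_band} must be smaller than cutoff {cutoff}"
        )
    segments: list[CnvSegment] = []
    for chrom, sub in track.bins.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        log2 = sub["log2_ratio"].to_numpy(dtype=float)
        state = np.zeros(len(log2), dtype=int)  # +1 amp candidate, -1 del
        state[log2 >= entry] = 1
        state[log2 <= -entry] = -1
        # close single-bin gaps: one sub-threshold bin flanked by
        # same-sign candidates joins the run (a lone Poisson dropout
        # must not split an aberrant segment)
        if len(state) > 2:
            interior = (
                (state[1:-1] == 0)
                & (state[:-2] == state[2:])
                & (state[:-2] != 0)
            )
            state[1:-1][interior] = state[:-2][interior]
        # maximal same-sign candidate runs; failures revert to neutral
        boundaries = np.flatnonzero(np.diff(state)) + 1
        run_edges = np.concatenate(([0], boundaries, [len(state)]))
        calls = np.zeros(len(state), dtype=int)
        for lo, hi in zip(run_edges[:-1], run_edges[1:]):
            s = state[lo]
            if s == 0 or hi - lo < min_bins:
                continue
            run = log2[lo:hi]
            if run.std(ddof=0) <= sd_band:
                calls[lo:hi] = s
        # emit segments tiling the chromosome
        boundaries = np.flatnonzero(np.diff(calls)) + 1
        run_edges = np.concatenate(([0], boundaries, [len(calls)]))
        for lo, hi in zip(run_edges[:-1], run_edges[1:]):
            run = log2[lo:hi]
            segments.append(
                CnvSegment(
                    chrom=str(chrom),
                    start=int(starts[lo]),
                    end=int(ends[hi - 1]),
                    state={1: "amplified", -1: "deleted", 0: "neutral"}[calls[lo]],
                    mean_log2=float(run.mean()),
                    sd_log2=float(run.std(ddof=0)),
                    n_bins=int(hi - lo),
                )
            )
    return segments


def annotate_segments(
    segments: Sequence[CnvSegment], gene_model: Sequence[GeneModel]
) -> list[tuple[CnvSegment, list[str]]]:
    """Genes whose interval overlaps each segment by at least one base
    (half-open coordinates: abutting intervals do not overlap)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_model:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for seg in segments:
        genes = [
            g.gene
            for g in by_chrom.get(seg.chrom, [])
            if max(seg.start, g.start) < min(seg.end, g.end)
        ]
        out.append((seg, sorted(genes)))
    return out


def gene_cnv_states(
    segments_by_group: Mapping[str, Sequence[CnvSegment]],
    gene_model: Sequence[GeneModel],
) -> dict[str, dict[str, str]]:
    """Per-group gene -> state map from annotated aberrant segments.

    A gene overlapping any amplified (deleted) segment of a group is
    amplified (deleted) there; amplification wins on (pathological)
    overlap of both; everything else is neutral.
    """
    states: dict[str, dict[str, str]] = {}
    for group, segments in segments_by_group.items():
        gmap: dict[str, str] = {}
        for seg, genes in annotate_segments(
            [s for s in segments if s.state != "neutral"], gene_model
        ):
            for gene in genes:
                if gmap.get(gene) != "amplified":
                    gmap[gene] = seg.state
        states[group] = gmap
    return states


def cnv_expression_concordance(
    gene_states: Mapping[str, Mapping[str, str]],
    expr: ExpressionMatrix,
    manifest: CohortManifest,
    g1: str,
    g2: str,
) -> pd.DataFrame:
    """Per-gene agreement of CNV state with relative expression.

    For every gene aberrant in either group: its CNV state and mean
    FPKM per group, plus ``concordant`` — true when the amplified side
    has the higher mean FPKM (deleted side the lower).  Genes neutral
    in both groups are omitted; an empty state map yields an empty
    table.
    """
    genes = sorted(set(gene_states.get(g1, {})) | set(gene_states.get(g2, {})))
    fpkm = expr.values
    rows = []
    for gene in genes:
        s1 = gene_states.get(g1, {}).get(gene, "neutral")
        s2 = gene_states.get(g2, {}).get(gene, "neutral")
        means = {}
        for g in (g1, g2):
            samples = [s for s in manifest.samples_in(g) if s in fpkm.columns]
            means[g] = (
                float(fpkm.loc[gene, samples].mean())
                if gene in fpkm.index and samples
                else np.nan
            )
        concordant: object
        if np.isnan(means[g1]) or np.isnan(means[g2]):
            concordant = np.nan
        else:
            verdicts = []
            for state, own, other in ((s1, means[g1], means[g2]),
                                      (s2, means[g2], means[g1])):
                if state == "amplified":
                    verdicts.append(own > other)
                elif state == "deleted":
                    verdicts.append(own < other)
            concordant = all(verdicts) if verdicts else True
        rows.append(
            {
                "gene": gene,
                f"cnv_{g1}": s1,
                f"cnv_{g2}": s2,
                f"mean_fpkm_{g1}": means[g1],
                f"mean_fpkm_{g2}": means[g2],
                "concordant": concordant,
            }
        )
    columns = ["gene", f"cnv_{g1}", f"cnv_{g2}",
               f"mean_fpkm_{g1}", f"mean_fpkm_{g2}", "concordant"]
    return pd.DataFrame(rows, columns=columns).set_index("gene") if rows else \
        pd.DataFrame(columns=columns[1:], index=pd.Index([], name="gene"))


def write_segments_bed(segments: Sequence[CnvSegment], path: str | Path) -> None:
    """BED5: name carries the state, score is mean log2 ratio x 1000."""
    with open(path, "w", encoding="utf-8") as fh:
        for seg in segments:
            fh.write(
                f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.state}\t"
                f"{int(round(seg.mean_log2 * 1000))}\n"
            )
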