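import numpy as np
import pandas as pd
import pytest

from gbmcontrast.cohort import CohortManifest, CoverageTrack, ExpressionMatrix, GeneModel
from gbmcontrast.cnv import (
    CnvSegment,
    CnvTrack,
    annotate_segments,
    call_segments,
    cnv_expression_concordance,
    gene_cnv_states,
    group_contrast_track,
    log2_ratio_track,
)
from gbmcontrast.synthetic import CohortConfig, CnvRegionSpec, generate_cohort


def track_from_counts(sample_id, counts, bin_size=1000, chrom="chr1"):
    n = len(counts)
    return CoverageTrack(
        sample_id,
        pd.DataFrame(
            {
                "chrom": [chrom] * n,
                "start": np.arange(n) * bin_size,
                "end": (np.arange(n) + 1) * bin_size,
                "count": counts,
            }
        ),
    )


def cnv_from_values(values, chrom="chr1", bin_size=1000):
    n = len(values)
    return CnvTrack(
        bins=pd.DataFrame(
            {
                "chrom": [chrom] * n,
                "start": np.arange(n) * bin_size,
                "end": (np.arange(n) + 1) * bin_size,
                "log2_ratio": values,
            }
        ),
        test_ids=("t",),
        control_ids=("c",),
    )


class TestLog2RatioTrack:
    def test_identical_tracks_give_zero(self, rng):
        counts = rng.poisson(100, size=50)
        counts[counts == 0] = 1
        t = track_from_counts("t", counts)
        c = track_from_counts("c", counts.copy())
        track = log2_ratio_track(t, c)
        assert np.allclose(track.bins["log2_ratio"], 0.0)

    def test_scale_invariance_is_exact(self, rng):
        counts = rng.poisson(100, size=50) + 1
        other = rng.poisson(120, size=50) + 1
        base = log2_ratio_track(
            track_from_counts("t", counts), track_from_counts("c", other)
        )
        scaled = log2_ratio_track(
            track_from_counts("t", counts * 7), track_from_counts("c", other * 3)
        )
        assert np.array_equal(
            base.bins["log2_ratio"].to_numpy(),
            scaled.bins["log2_ratio"].to_numpy(),
        )

    def test_doubled_control_still_zero(self, rng):
        counts = rng.poisson(100, size=40) + 1
        track = log2_ratio_track(
            track_from_counts("t", counts), track_from_counts("c", counts * 2)
        )
        assert np.allclose(track.bins["log2_ratio"], 0.0)

    def test_binning_mismatch_rejected(self, rng):
        t = track_from_counts("t", [10, 10, 10])
        c = track_from_counts("c", [10, 10])
        with pytest.raises(ValueError, match="binning mismatch"):
            log2_ratio_track(t, c)

    def test_planted_amplification_near_log2_one(self, rng):
        counts = np.full(200, 100)
        amped = counts.copy()
        amped[50:80] *= 2
        track = log2_ratio_track(
            track_from_counts("t", rng.poisson(amped)),
            track_from_counts("c", rng.poisson(counts)),
        )
        log2 = track.bins["log2_ratio"].to_numpy()
        assert log2[50:80].mean() == pytest.approx(1.0, abs=0.15)
        assert np.abs(np.delete(log2, slice(50, 80)).mean()) < 0.1


class TestGroupContrast:
    def test_swap_negates_exactly(self, rng):
        g1 = [track_from_counts(f"a{i}", rng.poisson(100, 60) + 1) for i in range(3)]
        g2 = [track_from_counts(f"b{i}", rng.poisson(100, 60) + 1) for i in range(2)]
        fwd = group_contrast_track(g1, g2).bins["log2_ratio"].to_numpy()
        rev = group_contrast_track(g2, g1).bins["log2_ratio"].to_numpy()
        assert np.array_equal(fwd, -rev)

    def test_equal_amplification_in_both_groups_cancels(self, rng):
        lam = np.full(100, 100.0)
        lam[20:50] *= 2  # same aberration in every sample of both groups
        g1 = [track_from_counts(f"a{i}", rng.poisson(lam)) for i in range(4)]
        g2 = [track_from_counts(f"b{i}", rng.poisson(lam)) for i in range(4)]
        track = group_contrast_track(g1, g2)
        segments = call_segments(track, cutoff=0.8)
        assert all(s.state == "neutral" for s in segments)


class TestCallSegments:
    def test_flat_track_one_neutral_segment_per_chromosome(self):
        values = np.zeros(30)
        track = cnv_from_values(values)
        segments = call_segments(track, cutoff=1.0)
        assert len(segments) == 1
        seg = segments[0]
        assert (seg.state, seg.n_bins) == ("neutral", 30)

    def test_segments_tile_binned_territory(self, rng):
        values = rng.normal(0, 0.6, size=120)
        track = cnv_from_values(values)
        segments = call_segments(track, cutoff=1.0)
        assert sum(s.n_bins for s in segments) == 120
        # contiguous, sorted, disjoint
        edges = [(s.start, s.end) for s in segments]
        for (s0, e0), (s1, e1) in zip(edges, edges[1:]):
            assert e0 == s1

    def test_planted_run_called_with_exact_bounds(self):
        values = np.zeros(60)
        values[10:30] = 1.0
        segments = call_segments(cnv_from_values(values), cutoff=1.0)
        amp = [s for s in segments if s.state == "amplified"]
        assert len(amp) == 1
        assert (amp[0].start, amp[0].end) == (10_000, 30_000)
        values[40:50] = -1.2
        segments = call_segments(cnv_from_values(values), cutoff=1.0)
        assert [s.state for s in segments if s.state != "neutral"] == [
            "amplified", "deleted",
        ]

    def test_noisy_run_filtered_by_sd_band(self):
        values = np.zeros(40)
        values[10:20] = np.tile([0.6, 2.4], 5)  # mean 1.5 but sd 0.9 > 0.5
        segments = call_segments(cnv_from_values(values), cutoff=1.0, sd_band=0.5)
        assert all(s.state == "neutral" for s in segments)

    def test_short_run_below_min_bins_not_called(self):
        values = np.zeros(40)
        values[10:13] = 1.5
        segments = call_segments(cnv_from_values(values), cutoff=1.0, min_bins=5)
        assert all(s.state == "neutral" for s in segments)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            call_segments(cnv_from_values(np.zeros(10)), cutoff=0.0)


class TestRecovery:
    def test_planted_two_fold_amplification_jaccard(self):
        """Seeded 2x amplification, >= 20 bins at depth 100, recovered at
        cut-off 1.0 with Jaccard >= 0.9 against the planted region."""
        config = CohortConfig(
            seed=13,
            cnv_regions=[CnvRegionSpec(0, 100, 130, 2.0, ("S", "L"))],
        )
        cohort = generate_cohort(config)
        track = log2_ratio_track(list(cohort.coverage.values()), cohort.normal)
        segments = call_segments(track, cutoff=1.0)
        amp = [s for s in segments if s.state == "amplified"]
        assert len(amp) == 1
        chrom, start, end, _, _ = cohort.truth.cnv_regions[0]
        seg = amp[0]
        assert seg.chrom == chrom
        inter = max(0, min(seg.end, end) - max(seg.start, start))
        union = max(seg.end, end) - min(seg.start, start)
        assert inter / union >= 0.9


class TestAnnotation:
    GENES = [
        GeneModel("IN", "chr1", 12_000, 14_000),
        GeneModel("EDGE", "chr1", 30_000, 31_000),   # abuts segment end
        GeneModel("OUT", "chr1", 50_000, 51_000),
        GeneModel("OTHER", "chr2", 12_000, 14_000),
    ]
    SEG = CnvSegment("chr1", 10_000, 30_000, "amplified", 1.0, 0.1, 20)

    def test_overlap_rules_half_open(self):
        (seg, genes), = annotate_segments([self.SEG], self.GENES)
        assert genes == ["IN"]

    def test_matches_all_pairs_overlap(self, rng):
        genes = [
            GeneModel(f"G{i}", "chr1", int(s), int(s) + int(l))
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 90_000, 40), rng.integers(1, 8_000, 40))
            )
        ]
        segments = [
            CnvSegment("chr1", int(s), int(s) + int(l), "amplified", 1.0, 0.1, 5)
            for s, l in zip(rng.integers(0, 90_000, 10), rng.integers(1, 20_000, 10))
        ]
        got = annotate_segments(segments, genes)
        for seg, hit in got:
            expected = sorted(
                g.gene for g in genes
                if max(seg.start, g.start) < min(seg.end, g.end)
            )
            assert hit == expected


class TestConcordance:
    MANIFEST = CohortManifest(
        [("a", "S", 2), ("b", "S", 3), ("f", "L", 30), ("g", "L", 32)]
    )

    def _expr(self, gene_values):
        return ExpressionMatrix(
            pd.DataFrame(gene_values, index=["a", "b", "f", "g"]).T.astype(float)
        )

    def test_amplified_with_higher_expression_concordant(self):
        expr = self._expr({"G1": [50, 60, 5, 6]})
        table = cnv_expression_concordance(
            {"S": {"G1": "amplified"}, "L": {}}, expr, self.MANIFEST, "S", "L"
        )
        assert bool(table.loc["G1", "concordant"]) is True

    def test_amplified_with_flat_expression_discordant(self):
        expr = self._expr({"G1": [5, 6, 5, 6]})
        table = cnv_expression_concordance(
            {"S": {"G1": "amplified"}, "L": {}}, expr, self.MANIFEST, "S", "L"
        )
        assert bool(table.loc["G1", "concordant"]) is False

    def test_empty_states_give_empty_table(self):
        expr = self._expr({"G1": [1, 1, 1, 1]})
        table = cnv_expression_concordance(
            {"S": {}, "L": {}}, expr, self.MANIFEST, "S", "L"
        )
        assert len(table) == 0

    def test_gene_states_from_segments(self):
        genes = [GeneModel("G1", "chr1", 12_000, 14_000)]
        segments = {
            "S": [CnvSegment("chr1", 10_000, 30_000, "amplified", 1.0, 0.1, 20)],
            "L": [CnvSegment("chr1", 10_000, 30_000, "neutral", 0.0, 0.1, 20)],
        }
        states = gene_cnv_states(segments, genes)
        assert states == {"S": {"G1": "amplified"}, "L": {}}
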