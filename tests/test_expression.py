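import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gbmcontrast.burden import build_gene_burden_matrix
from gbmcontrast.cohort import CohortManifest, ExpressionMatrix
from gbmcontrast.expression import (
    DegTable,
    bh_qvalues,
    common_degs,
    differential_expression,
    integrate,
    three_group_screen,
    venn_partition,
)
from gbmcontrast.synthetic import CohortConfig, generate_cohort
from conftest import make_record
from oracle_helpers import brute_bh


MANIFEST = CohortManifest(
    [("a", "S", 2), ("b", "S", 3), ("c", "S", 4),
     ("d", "M", 16), ("e", "M", 18),
     ("f", "L", 30), ("g", "L", 32)]
)


def expr_from_rows(rows: dict) -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(rows, index=MANIFEST.sample_ids).T.astype(float)
    )


class TestBenjaminiHochberg:
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_matches_brute_force_step_up(self, p_values):
        assert bh_qvalues(p_values) == pytest.approx(
            brute_bh(p_values), rel=1e-12, abs=1e-12
        )

    def test_q_at_least_p_and_monotone_in_rank(self, rng):
        p = rng.uniform(size=50)
        q = bh_qvalues(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestDifferentialExpression:
    def test_identical_groups_zero_noise_nothing_significant(self):
        expr = expr_from_rows({f"G{i}": [5.0] * 7 for i in range(10)})
        table = differential_expression(expr, MANIFEST, ("S", "L"))
        assert table.significant_genes == set()
        assert (table.frame["p_value"] == 1.0).all()

    def test_clean_shift_detected(self):
        rows = {f"G{i}": [8.0] * 7 for i in range(20)}
        rows["G0"] = [64.0, 64.0, 64.0, 8.0, 8.0, 8.0, 8.0]  # S high
        table = differential_expression(expr_from_rows(rows), MANIFEST, ("S", "L"))
        assert table.significant_genes == {"G0"}
        assert table.frame.loc["G0", "log2fc"] == pytest.approx(3.0, abs=0.2)

    def test_side_with_one_sample_rejected(self):
        manifest = CohortManifest([("a", "S", 2), ("f", "L", 30), ("g", "L", 32)])
        expr = ExpressionMatrix(
            pd.DataFrame({"a": [1.0], "f": [1.0], "g": [1.0]}, index=["G0"])
        )
        with pytest.raises(ValueError, match=">= 2 samples"):
            differential_expression(expr, manifest, ("S", "L"))

    def test_planted_recovery_under_noise(self):
        """High-signal noisy generator run: sensitivity >= 0.95 at
        FDR <= 0.1 against the planted S-vs-L differential genes."""
        config = CohortConfig(
            seed=5, deg_delta=4.0, expression_noise_sd=0.5,
            n_mutated_union=100, n_deg_sl_only=20, n_deg_triple=0,
            n_deg_sm_ml=5,
        )
        cohort = generate_cohort(config)
        table = differential_expression(
            cohort.expression, cohort.manifest, ("S", "L")
        )
        truth = cohort.truth.deg_sl_only
        found = table.significant_genes
        sensitivity = len(found & truth) / len(truth)
        false_positives = found - truth - cohort.truth.deg_triple
        fdr = len(false_positives) / max(len(found), 1)
        assert sensitivity >= 0.95
        assert fdr <= 0.1

    def test_null_noise_type_one_rate_near_alpha(self):
        """With no planted signal the per-gene p-values are uniform."""
        config = CohortConfig(
            seed=9, expression_noise_sd=0.5, n_genes=400,
            n_mutated_s=10, n_mutated_l=8, n_mutated_union=14,
            n_recurrent={"S": 0, "L": 0}, n_hyper={"S": 0, "L": 0},
            n_exclusive_shared_variants={"S": 0, "L": 0},
            n_universal_variants=0,
            total_occurrences={"S": 40, "L": 30},
            n_coding={"S": 28, "L": 21}, n_deleterious={"S": 20, "L": 15},
            n_deg_sl_only=0, n_deg_triple=0, n_deg_sm_ml=0,
        )
        cohort = generate_cohort(config)
        table = differential_expression(
            cohort.expression, cohort.manifest, ("S", "L")
        )
        frac = (table.frame["p_value"] < 0.05).mean()
        assert 0.01 <= frac <= 0.12

    def test_three_group_screen_flags_any_shift(self):
        rows = {f"G{i}": [4.0] * 7 for i in range(10)}
        rows["G3"] = [4.0, 4.0, 4.0, 64.0, 64.0, 4.0, 4.0]  # M shifted
        table = three_group_screen(expr_from_rows(rows), MANIFEST)
        assert table.significant_genes == {"G3"}


def deg_from_sets(universe, significant, comparison=("S", "L")):
    frame = pd.DataFrame(
        {
            "mean_a": 1.0, "mean_b": 1.0, "log2fc": 0.0,
            "p_value": [0.0 if g in significant else 1.0 for g in universe],
            "q_value": [0.0 if g in significant else 1.0 for g in universe],
            "significant": [g in significant for g in universe],
        },
        index=pd.Index(universe, name="gene"),
    )
    return DegTable(comparison=comparison, frame=frame)


class TestVennPartition:
    def test_disjoint_sets_fill_pure_regions(self):
        universe = [f"G{i}" for i in range(9)]
        venn = venn_partition(
            deg_from_sets(universe, {"G0", "G1"}),
            deg_from_sets(universe, {"G2"}, ("S", "M")),
            deg_from_sets(universe, {"G3", "G4", "G5"}, ("M", "L")),
        )
        assert venn.region_counts == {
            "SL": 2, "SM": 1, "ML": 3,
            "SL&SM": 0, "SL&ML": 0, "SM&ML": 0, "SL&SM&ML": 0,
        }
        assert venn.total == 6

    def test_matches_membership_enumeration(self, rng):
        universe = [f"G{i}" for i in range(30)]
        for _ in range(10):
            sets = [
                set(rng.choice(universe, size=rng.integers(0, 20), replace=False))
                for _ in range(3)
            ]
            venn = venn_partition(
                deg_from_sets(universe, sets[0]),
                deg_from_sets(universe, sets[1], ("S", "M")),
                deg_from_sets(universe, sets[2], ("M", "L")),
            )
            union = sets[0] | sets[1] | sets[2]
            assert venn.total == len(union)
            assert sum(venn.region_counts.values()) == len(union)
            for gene in union:
                member = tuple(gene in s for s in sets)
                region = "&".join(
                    l for l, m in zip(("SL", "SM", "ML"), member) if m
                )
                assert gene in venn.genes_in_region(region)

    def test_row_order_invariance(self, rng):
        universe = [f"G{i}" for i in range(20)]
        sig = set(universe[::3])
        tables = [
            deg_from_sets(universe, sig),
            deg_from_sets(universe, set(universe[::4]), ("S", "M")),
            deg_from_sets(universe, set(universe[::5]), ("M", "L")),
        ]
        shuffled = [
            DegTable(t.comparison, t.frame.sample(frac=1, random_state=1))
            for t in tables
        ]
        assert venn_partition(*tables).region_counts == venn_partition(
            *shuffled
        ).region_counts

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            venn_partition(
                deg_from_sets(["G0"], set()),
                deg_from_sets(["G1"], set(), ("S", "M")),
                deg_from_sets(["G0"], set(), ("M", "L")),
            )


class TestCommonDegs:
    def test_empty_first_set(self):
        universe = ["G0", "G1"]
        assert common_degs(
            deg_from_sets(universe, set(), ("M", "rest")),
            deg_from_sets(universe, {"G0"}),
        ) == set()

    def test_intersection(self):
        universe = [f"G{i}" for i in range(6)]
        got = common_degs(
            deg_from_sets(universe, {"G0", "G1", "G2"}, ("M", "rest")),
            deg_from_sets(universe, {"G1", "G2", "G4"}),
        )
        assert got == {"G1", "G2"}


class TestIntegrate:
    def test_joins_all_layers(self):
        manifest = CohortManifest(
            [("a", "S", 2), ("b", "S", 3), ("f", "L", 30), ("g", "L", 32)]
        )
        records = [
            make_record(sample_id=s, pos=100 + i, gene="GENE1")
            for i, s in enumerate(("a", "b"))
        ]
        matrix = build_gene_burden_matrix(records, manifest)
        expr = ExpressionMatrix(
            pd.DataFrame(
                {"a": [80.0, 1.0], "b": [60.0, 1.0],
                 "f": [5.0, 1.0], "g": [3.0, 1.0]},
                index=["GENE1", "GENE2"],
            )
        )
        report = integrate(
            matrix,
            {"S": {"GENE1"}, "L": set()},
            {"S": {"GENE1": "amplified"}},
            expr,
            manifest,
            ["GENE1", "GENE2", "ABSENT"],
        )
        row = report.loc["GENE1"]
        assert row["n_variants_S"] == 2 and row["n_variants_L"] == 0
        assert row["hypermutated_S"] and row["cnv_S"] == "amplified"
        assert row["mean_fpkm_S"] == pytest.approx(70.0)
        # absent gene retained with missing expression, not dropped
        assert "ABSENT" in report.index
        assert np.isnan(report.loc["ABSENT", "mean_fpkm_S"])

    def test_all_null_gene_row(self):
        manifest = CohortManifest([("a", "S", 2), ("b", "S", 3)])
        matrix = build_gene_burden_matrix([], manifest)
        report = integrate(matrix, {}, {}, None, manifest, ["GENE9"])
        row = report.loc["GENE9"]
        assert row["n_variants_S"] == 0
        assert row["cnv_S"] == "neutral"
        assert row["expression_tier"] == "missing"
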