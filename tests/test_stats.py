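"""Rank-sum tests, BH correction, score comparisons and marker detection."""

import numpy as np
import pytest

from scgps import (
    BY_CLUSTER,
    BY_GENOTYPE,
    DataError,
    GeneSetCollection,
    ScoreTable,
    bh_adjust,
    compare_scores,
    find_markers,
    normalize_log,
    rank_sum_test,
    results_to_frame,
)
from helpers import make_cells, make_counts, make_lognorm
from oracles import brute_bh, exhaustive_rank_sum_p


class TestRankSumTest:
    def test_complete_separation_exact_p(self):
        # only 2 of the C(6,3)=20 labelings are as extreme → p = 0.1
        stat, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert stat == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets_p_one(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_fully_tied_degenerate(self):
        stat, p = rank_sum_test([5.0], [5.0])
        assert p == 1.0
        assert stat == 0.5  # null mean of U for 1×1

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            rank_sum_test([], [1.0])

    def test_normal_approximation_close_to_exact_small_samples(self, rng):
        """Tie-free pooled sizes ≤ 16: the continuity-corrected normal p stays
        close to exact enumeration — within 0.04 everywhere (the worst case,
        0.0375, occurs at 3 vs 3) and within 0.03 once both groups have ≥5."""
        for _ in range(60):
            n_a = int(rng.integers(3, 9))
            n_b = int(rng.integers(3, 9))
            pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1))
            a, b = pooled[:n_a], pooled[n_a:]
            _, p_exact = rank_sum_test(a, b, exact_threshold=16)
            _, p_approx = rank_sum_test(a, b, exact_threshold=0)
            assert abs(p_exact - p_approx) < 0.04
            if min(n_a, n_b) >= 5:
                assert abs(p_exact - p_approx) < 0.03

    def test_type_one_error_calibrated_under_null(self, rng):
        """Both groups from the same distribution: ~5% rejections at α=0.05."""
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.normal(size=25)
            b = rng.normal(size=25)
            _, p = rank_sum_test(a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03], atol=1e-12)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_cap_at_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])

    def test_matches_stepup_oracle_and_dominates_raw(self, rng):
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 40)))
            adj = bh_adjust(p)
            np.testing.assert_allclose(adj, brute_bh(p), atol=1e-12)
            assert (adj >= p - 1e-15).all()
            # adjusted values are a monotone transform of the raw ranks
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-15).all()


def _score_table(values, set_name="S"):
    values = np.asarray(values, dtype=float)
    return ScoreTable(scores=values.reshape(-1, 1),
                      cell_ids=[f"c{i}" for i in range(len(values))],
                      set_names=[set_name], genes_used={set_name: 5})


class TestCompareScores:
    def test_separated_cluster_detected(self, rng):
        scores = np.concatenate([rng.uniform(0.6, 0.9, 30), rng.uniform(0.1, 0.4, 30)])
        cells = make_cells([f"c{i}" for i in range(60)],
                           cluster=["A"] * 30 + ["B"] * 30)
        res = compare_scores(_score_table(scores), cells, design=BY_CLUSTER)
        by_group = {r.group_a: r for r in res}
        assert by_group["A"].effect > 0
        assert by_group["A"].p_value < 0.05
        assert by_group["A"].p_adjusted >= by_group["A"].p_value

    def test_constant_scores_give_p_one_effect_zero(self):
        cells = make_cells([f"c{i}" for i in range(20)],
                           cluster=["A"] * 10 + ["B"] * 10)
        res = compare_scores(_score_table([0.3] * 20), cells)
        assert all(r.p_value == 1.0 and r.effect == 0.0 for r in res)

    def test_single_cluster_is_data_error(self):
        cells = make_cells([f"c{i}" for i in range(4)], cluster=["A"] * 4)
        with pytest.raises(DataError, match="2 clusters"):
            compare_scores(_score_table([0.1, 0.2, 0.3, 0.4]), cells)

    def test_swapping_groups_negates_effect_preserves_p(self, rng):
        a = rng.random(12)
        b = rng.random(15)
        from scgps.stats import _contrast
        r1 = _contrast("S", "A", "B", a, b, 16, "two-sided")
        r2 = _contrast("S", "B", "A", b, a, 16, "two-sided")
        assert r1.effect == pytest.approx(-r2.effect)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_genotype_within_cluster_skips_empty_groups(self, rng):
        n = 40
        cluster = ["A"] * 20 + ["B"] * 20
        genotype = ["WT", "KO"] * 10 + ["WT"] * 20  # cluster B has no KO cells
        cells = make_cells([f"c{i}" for i in range(n)], cluster=cluster,
                           genotype=genotype)
        res = compare_scores(_score_table(rng.random(n)), cells, design=BY_GENOTYPE)
        assert len(res) == 1  # only cluster A has both genotypes
        assert res[0].group_a.startswith("WT")

    def test_results_frame_has_fixed_column_order(self, rng):
        cells = make_cells([f"c{i}" for i in range(10)],
                           cluster=["A"] * 5 + ["B"] * 5)
        df = results_to_frame(compare_scores(_score_table(rng.random(10)), cells))
        assert list(df.columns) == ["unit", "group_a", "group_b", "n_a", "n_b",
                                    "statistic", "effect", "p_value", "p_adjusted"]


class TestFindMarkers:
    def _planted(self, rng):
        # gene 0 expressed only in cluster A; the rest is uniform background
        counts = rng.integers(1, 4, size=(20, 40))
        counts[0] = 0
        counts[0, :20] = rng.integers(5, 15, size=20)
        ln = normalize_log(make_counts(counts))
        cells = make_cells([f"c{i}" for i in range(40)],
                           cluster=["A"] * 20 + ["B"] * 20)
        return ln, cells

    def test_planted_marker_is_top_hit_with_positive_effect(self, rng):
        ln, cells = self._planted(rng)
        res = find_markers(ln, cells)
        top_a = [r for r in res if r.group_a == "A"][0]
        assert top_a.unit == "g0"
        assert top_a.effect > 0
        assert top_a.p_adjusted < 0.01

    def test_gene_below_min_pct_absent(self, rng):
        ln, cells = self._planted(rng)
        counts = np.asarray(np.expm1(ln.values.todense()))  # sanity anchor only
        res = find_markers(ln, cells, min_pct=1.01)  # impossible threshold
        assert res == []

    def test_filter_bypass_tests_every_gene(self, rng):
        ln, cells = self._planted(rng)
        res = find_markers(ln, cells, min_pct=0.0, min_effect=0.0)
        tested_units = {r.unit for r in res if r.group_a == "A"}
        assert tested_units == {f"g{i}" for i in range(20)}

    def test_oracle_p_matches_exhaustive_enumeration_tiny(self):
        # independent cross-check of the tie-free exact path at a tiny size
        a = [0.1, 0.9, 0.5, 0.7]
        b = [0.2, 0.3, 0.05]
        _, p = rank_sum_test(a, b)
        assert p == pytest.approx(exhaustive_rank_sum_p(a, b), abs=1e-12)
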