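import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from skbio.diversity.alpha import shannon as skbio_shannon

from oralvirome.diversity import (
    DistanceMatrix,
    boxplot_stats,
    bray_curtis_matrix,
    compare_alpha,
    compare_beta,
    fdr_bh,
    permutation_t_test,
    shannon,
)
from oralvirome.errors import ValidationError
from oralvirome.tables import TaxonTable


class TestShannon:
    def test_uniform_four_taxa_is_two_bits(self):
        assert shannon([10, 10, 10, 10]) == pytest.approx(2.0)

    def test_single_taxon_is_zero(self):
        assert shannon([42]) == 0.0

    def test_three_quarters_split(self):
        # −0.75·log2 0.75 − 0.25·log2 0.25
        assert shannon([75, 25]) == pytest.approx(0.8112781, abs=1e-6)

    def test_zero_count_taxa_do_not_change_h(self):
        assert shannon([5, 3, 0, 0]) == pytest.approx(shannon([5, 3]))

    def test_maximal_iff_uniform(self):
        rng = np.random.default_rng(1)
        uniform = shannon([7, 7, 7, 7, 7])
        for _ in range(20):
            counts = rng.integers(1, 50, 5)
            assert shannon(counts) <= uniform + 1e-12
        assert uniform == pytest.approx(np.log2(5))

    def test_all_zero_vector_is_error(self):
        with pytest.raises(ValidationError):
            shannon([0, 0])

    def test_agrees_with_skbio(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            counts = rng.integers(0, 40, 8)
            if counts.sum() == 0:
                continue
            assert shannon(counts) == pytest.approx(
                float(skbio_shannon(counts, base=2))
            )


class TestBrayCurtis:
    def test_identical_columns_give_zero(self):
        table = TaxonTable(
            "species", pd.DataFrame({"S1": [3, 7], "S2": [3, 7]}, index=["a", "b"])
        )
        assert bray_curtis_matrix(table).data[0, 1] == 0.0

    def test_disjoint_supports_give_one(self):
        table = TaxonTable(
            "species", pd.DataFrame({"S1": [5, 0], "S2": [0, 9]}, index=["a", "b"])
        )
        assert bray_curtis_matrix(table).data[0, 1] == 1.0

    def test_hand_computed_case(self):
        table = TaxonTable(
            "species", pd.DataFrame({"S1": [6, 4], "S2": [2, 8]}, index=["a", "b"])
        )
        # (|6−2| + |4−8|) / (10 + 10) = 8/20
        assert bray_curtis_matrix(table).data[0, 1] == pytest.approx(0.4)

    def test_symmetry_zero_diagonal_and_range(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(10, 6)),
            index=[f"t{i}" for i in range(10)],
            columns=[f"S{j}" for j in range(6)],
        )
        dm = bray_curtis_matrix(TaxonTable("species", counts))
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0)
        assert ((dm.data >= 0) & (dm.data <= 1)).all()

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(
            rng.integers(1, 50, size=(12, 5)),
            columns=[f"S{j}" for j in range(5)],
        )
        dm = bray_curtis_matrix(TaxonTable("species", counts))
        X = counts.to_numpy(float)
        for i in range(5):
            for j in range(5):
                if i != j:
                    assert dm.data[i, j] == pytest.approx(
                        scipy_braycurtis(X[:, i], X[:, j])
                    )

    def test_identical_composition_different_depth_zero_after_normalising(self):
        counts = pd.DataFrame({"S1": [20, 80], "S2": [200, 800]}, index=["a", "b"])
        proportions = counts / counts.sum(axis=0)
        dm = bray_curtis_matrix(proportions)
        assert dm.data[0, 1] == pytest.approx(0.0)

    def test_all_zero_pair_flagged(self):
        table = TaxonTable(
            "species",
            pd.DataFrame({"S1": [1, 0], "S2": [0, 0], "S3": [0, 0]}, index=["a", "b"]),
        )
        dm = bray_curtis_matrix(table)
        assert dm.undefined_pairs == (("S2", "S3"),)

    def test_skbio_view_round_trips(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 0.3], [0.3, 0.0]]))
        assert dm.to_skbio()["a", "b"] == pytest.approx(0.3)


class TestPermutationTTest:
    def test_identical_multisets_give_p_one(self):
        values = [1.0, 2.0, 3.0, 4.0]
        t, p = permutation_t_test(values, list(values), 199, np.random.default_rng(0))
        assert t == 0.0 and p == 1.0

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 30)
        y = rng.normal(5, 1, 30)  # 5 pooled SDs apart
        _, p = permutation_t_test(x, y, 999, np.random.default_rng(1))
        assert p <= 0.01

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 1, 12)
        t_xy, p_xy = permutation_t_test(x, y, 999, np.random.default_rng(9))
        t_yx, p_yx = permutation_t_test(y, x, 999, np.random.default_rng(9))
        assert t_xy == pytest.approx(-t_yx)
        # Monte Carlo estimates of the same exhaustive p: equal to within
        # three binomial standard errors of the permutation draw.
        se = np.sqrt(max(p_xy * (1 - p_xy), 0.01) / 1000)
        assert abs(p_xy - p_yx) <= 3 * se

    def test_add_one_estimator_never_zero(self):
        x = [0.0] * 5
        y = [100.0] * 5
        _, p = permutation_t_test(x, y, 99, np.random.default_rng(0))
        assert p >= 1 / 100

    def test_null_rejection_rate_calibrated(self):
        """Under a true null the permutation p is (super-)uniform: the
        rejection rate at α = 0.05 over 500 simulations stays in
        [0.02, 0.08]."""
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(500):
            x = rng.normal(0, 1, 10)
            y = rng.normal(0, 1, 10)
            _, p = permutation_t_test(x, y, 99, rng)
            rejections += p <= 0.05
        assert 0.02 <= rejections / 500 <= 0.08


class TestCompareAlpha:
    def test_fdr_applied_across_comparisons(self):
        rng = np.random.default_rng(5)
        alpha = {f"S{i}": float(v) for i, v in enumerate(rng.normal(2, 0.5, 30))}
        groups = {f"S{i}": ["F", "M", "X"][i % 3] for i in range(30)}
        results = compare_alpha(alpha, groups, 199, seed=3)
        assert len(results) == 3  # three pairwise comparisons
        raw = [r.p_raw for r in results]
        adjusted = [r.p_adjusted for r in results]
        assert adjusted == pytest.approx(fdr_bh(raw))
        assert all(a >= r for a, r in zip(adjusted, raw))

    def test_reproducible_under_seed(self):
        alpha = {f"S{i}": float(i % 7) for i in range(20)}
        groups = {f"S{i}": "F" if i < 10 else "M" for i in range(20)}
        a = compare_alpha(alpha, groups, 199, seed=11)
        b = compare_alpha(alpha, groups, 199, seed=11)
        assert a[0].p_raw == b[0].p_raw


class TestFdrBH:
    def test_hand_computed_step_up(self):
        assert fdr_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_bh([0.2]) == pytest.approx([0.2])

    def test_equal_ps_unchanged(self):
        assert fdr_bh([0.04, 0.04, 0.04]) == pytest.approx([0.04, 0.04, 0.04])

    def test_adjusted_at_least_raw_and_monotone(self):
        raw = [0.001, 0.01, 0.02, 0.5, 0.9]
        adjusted = fdr_bh(raw)
        assert all(a >= r for a, r in zip(adjusted, raw))
        assert adjusted == sorted(adjusted)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_bh([0.5, 0.0])
        with pytest.raises(ValidationError):
            fdr_bh([1.5])


class TestCompareBeta:
    @staticmethod
    def _clustered_dm(n_per=6, within=0.1, between=0.9):
        ids = [f"F{i}" for i in range(n_per)] + [f"M{i}" for i in range(n_per)]
        n = 2 * n_per
        data = np.full((n, n), between)
        data[:n_per, :n_per] = within
        data[n_per:, n_per:] = within
        np.fill_diagonal(data, 0.0)
        groups = {s: s[0] for s in ids}
        return DistanceMatrix(tuple(ids), data), groups

    def test_constant_distances_give_p_one(self):
        dm, groups = self._clustered_dm(within=0.5, between=0.5)
        result = compare_beta(dm, groups, 199, seed=0)
        assert result.comparisons
        assert all(c.p_raw == 1.0 for c in result.comparisons)

    def test_separated_clusters_detected(self):
        dm, groups = self._clustered_dm()
        result = compare_beta(dm, groups, 999, seed=0)
        between_vs_within = [
            c
            for c in result.comparisons
            if c.group_a.startswith("between") or c.group_b.startswith("between")
        ]
        assert between_vs_within
        assert all(c.p_raw <= 0.01 for c in between_vs_within)

    def test_bonferroni_is_raw_times_comparisons_capped(self):
        rng = np.random.default_rng(4)
        n = 10
        raw = rng.uniform(0.2, 0.8, size=(n, n))
        data = np.clip((raw + raw.T) / 2, 0, 1)
        np.fill_diagonal(data, 0)
        ids = tuple(f"S{i}" for i in range(n))
        groups = {s: "F" if i < 5 else "M" for i, s in enumerate(ids)}
        result = compare_beta(DistanceMatrix(ids, data), groups, 199, seed=2)
        k = len(result.comparisons)
        for c in result.comparisons:
            assert c.p_adjusted == pytest.approx(min(1.0, c.p_raw * k))

    def test_boxplot_stats_five_numbers(self):
        stats = boxplot_stats([1.0, 2.0, 3.0, 4.0, 5.0])
        assert stats == {
            "min": 1.0, "q1": 2.0, "median": 3.0, "q3": 4.0, "max": 5.0,
        }

    def test_singleton_group_skipped_with_notice(self):
        ids = ("A1", "A2", "A3", "B1")
        data = np.array(
            [
                [0.0, 0.2, 0.3, 0.8],
                [0.2, 0.0, 0.25, 0.7],
                [0.3, 0.25, 0.0, 0.75],
                [0.8, 0.7, 0.75, 0.0],
            ]
        )
        groups = {s: s[0] for s in ids}
        result = compare_beta(DistanceMatrix(ids, data), groups, 199, seed=0)
        assert result.skipped  # within-B is empty
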