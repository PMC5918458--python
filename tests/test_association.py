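import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from exat.association import (
    analyze_all,
    approximation_panel,
    exat_statistic,
    fisher_exact_rx3,
    fisher_single_snv,
    normal_approx_pvalue,
    permutation_pvalue,
)
from exat.simulate import generate_ipmn_like_fixture
from exat.tables import GeneMap, GenotypeMatrix, build_subject_table

from oracles import exhaustive_label_pvalue


def _matrix(counts, labels):
    counts = np.asarray(counts)
    return GenotypeMatrix(
        [f"s{i}" for i in range(counts.shape[0])],
        [f"v{j}" for j in range(counts.shape[1])],
        counts, labels,
    )


class TestExatStatistic:
    def test_identical_groups_give_T_zero(self):
        tabs = [build_subject_table(g) for g in ([0, 1, 2], [1, 0, 1])]
        c1, c0, T = exat_statistic(tabs, list(tabs))
        assert c1 == pytest.approx(c0)
        assert T == pytest.approx(0.0, abs=1e-12)

    def test_group_swap_negates_T(self):
        rng = np.random.default_rng(3)
        a = [build_subject_table(g) for g in rng.integers(0, 3, (4, 4))]
        b = [build_subject_table(g) for g in rng.integers(0, 3, (5, 4))]
        _, _, T = exat_statistic(a, b)
        _, _, T_swap = exat_statistic(b, a)
        assert T_swap == pytest.approx(-T, abs=1e-12)

    def test_T_is_log_ratio(self):
        rng = np.random.default_rng(4)
        a = [build_subject_table(g) for g in rng.integers(0, 3, (4, 3))]
        b = [build_subject_table(g) for g in rng.integers(0, 3, (4, 3))]
        c1, c0, T = exat_statistic(a, b)
        assert T == pytest.approx(np.log(c1 / c0))

    def test_zero_statistic_flags_undefined(self):
        # constant-genotype subjects give a zero group statistic
        a = [build_subject_table([1, 1, 1]) for _ in range(3)]
        b = [build_subject_table(g) for g in ([0, 1, 2], [2, 1, 0])]
        c1, c0, T = exat_statistic(a, b)
        assert c1 == 0.0 and np.isnan(T)

    def test_empty_group_rejected(self):
        tabs = [build_subject_table([0, 1])]
        with pytest.raises(ValueError, match="non-empty"):
            exat_statistic(tabs, [])


class TestPermutationPvalue:
    def test_T_zero_gives_p_one(self):
        # identical case/control genotype blocks: T_obs = 0 exactly
        block = np.array([[0, 1, 2], [1, 0, 1]])
        m = _matrix(np.vstack([block, block]), [1, 1, 0, 0])
        res, _ = permutation_pvalue(m, m.variant_ids, B=200, seed=0)
        assert res.T == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_monte_carlo_matches_exhaustive_oracle(self, tiny_matrix):
        exact = exhaustive_label_pvalue(tiny_matrix)
        res, _ = permutation_pvalue(tiny_matrix, tiny_matrix.variant_ids,
                                    B=10_000, seed=5)
        se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(res.p_value - exact) <= 3 * se + 2e-4  # +1 correction slack

    def test_reproducible_given_seed(self, small_matrix):
        r1, _ = permutation_pvalue(small_matrix, small_matrix.variant_ids, B=500, seed=9)
        r2, _ = permutation_pvalue(small_matrix, small_matrix.variant_ids, B=500, seed=9)
        assert r1.p_value == r2.p_value and r1.T == r2.T

    def test_label_swap_keeps_pvalue(self, small_matrix):
        res, _ = permutation_pvalue(small_matrix, small_matrix.variant_ids, B=2000, seed=1)
        swapped = GenotypeMatrix(
            small_matrix.subject_ids, small_matrix.variant_ids,
            small_matrix.counts, 1 - small_matrix.labels,
        )
        res_s, _ = permutation_pvalue(swapped, swapped.variant_ids, B=2000, seed=1)
        assert res_s.T == pytest.approx(-res.T, abs=1e-12)
        # same two-sided p up to Monte-Carlo noise of the label draws
        assert abs(res_s.p_value - res.p_value) < 0.06

    def test_permuted_null_roughly_symmetric(self):
        rng = np.random.default_rng(17)
        m = _matrix(rng.integers(0, 3, (30, 8)), np.r_[np.ones(15), np.zeros(15)])
        _, null = permutation_pvalue(m, m.variant_ids, B=4000, seed=2)
        Tp = null.T_perm[~np.isnan(null.T_perm)]
        from scipy.stats import skew
        assert abs(float(skew(Tp))) < 0.5
        assert abs(Tp.mean()) < 0.2

    def test_undefined_observed_T_flagged(self):
        # cases all constant genotype -> CMH_case = 0 -> T undefined
        counts = np.array([[1, 1], [1, 1], [0, 1], [2, 1], [0, 2], [1, 0]])
        m = _matrix(counts, [1, 1, 0, 0, 0, 0])
        res, _ = permutation_pvalue(m, m.variant_ids, B=100, seed=0)
        assert res.undefined_T and np.isnan(res.p_value)


class TestNormalApproxPvalue:
    def test_close_to_permutation_reference(self):
        rng = np.random.default_rng(23)
        m = _matrix(rng.integers(0, 3, (24, 10)), np.r_[np.ones(12), np.zeros(12)])
        ref, _ = permutation_pvalue(m, m.variant_ids, B=20_000, seed=3)
        app = normal_approx_pvalue(m, m.variant_ids, B_small=2000, seed=4)
        assert app.p_value == pytest.approx(ref.p_value, abs=0.05)

    def test_moments_estimated_not_forced(self):
        rng = np.random.default_rng(29)
        m = _matrix(rng.integers(0, 3, (16, 6)), np.r_[np.ones(8), np.zeros(8)])
        res = normal_approx_pvalue(m, m.variant_ids, B_small=50, seed=0)
        assert np.isfinite(res.mu_hat) and res.sigma_hat > 0
        assert 0 < res.p_value <= 1

    def test_small_B_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="at least 10"):
            normal_approx_pvalue(small_matrix, small_matrix.variant_ids, B_small=5)


class TestFisherExact:
    def test_2x2_matches_scipy(self):
        for tab in ([[3, 0], [0, 3]], [[2, 5], [4, 1]], [[8, 2], [3, 7]]):
            ours = fisher_exact_rx3(np.array(tab))
            theirs = scipy_fisher(np.array(tab)).pvalue
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_most_probable_table_gives_p_one(self):
        # identical genotype distributions arranged as the modal table
        assert fisher_exact_rx3(np.array([[4, 2, 0], [4, 2, 0]])) == pytest.approx(1.0)

    def test_empty_columns_collapsed(self):
        with_empty = np.array([[3, 0, 2], [1, 0, 4]])
        collapsed = np.array([[3, 2], [1, 4]])
        assert fisher_exact_rx3(with_empty) == pytest.approx(
            fisher_exact_rx3(collapsed)
        )

    def test_matches_direct_enumeration(self):
        # independent check: direct probability-ordering enumeration with comb
        from math import comb
        tab = np.array([[2, 1, 3], [4, 2, 0]])
        cols = tab.sum(axis=0)
        r1, N = int(tab[0].sum()), int(tab.sum())
        denom = comb(N, r1)

        def prob(a, b, c):
            return comb(cols[0], a) * comb(cols[1], b) * comb(cols[2], c) / denom

        p_obs = prob(*tab[0])
        total = sum(
            prob(a, b, r1 - a - b)
            for a in range(cols[0] + 1)
            for b in range(cols[1] + 1)
            if 0 <= r1 - a - b <= cols[2]
            and prob(a, b, r1 - a - b) <= p_obs * (1 + 1e-9)
        )
        assert fisher_exact_rx3(tab) == pytest.approx(total, abs=1e-10)

    def test_single_snv_route(self):
        counts = np.array([[0], [2], [2], [0], [0], [1]])
        m = _matrix(counts, [1, 1, 1, 0, 0, 0])
        res = fisher_single_snv(m, "v0", gene_id="g")
        assert res.method == "fisher_exact" and 0 < res.p_value <= 1


@pytest.fixture(scope="module")
def study():
    matrix, _, gm = generate_ipmn_like_fixture(seed=8, n_subjects=20, n_case=10,
                                               n_genes=12)
    return matrix, gm


class TestAnalyzeAll:
    def test_one_row_per_gene_and_fisher_routing(self, study):
        matrix, gm = study
        out = analyze_all(matrix, gm, method="normal_approx", B_small=30, seed=1)
        assert len(out) == len(gm)
        t1 = out[out["t"] == 1]
        assert (t1["method"] == "fisher_exact").all()

    def test_rerun_bit_identical(self, study):
        matrix, gm = study
        a = analyze_all(matrix, gm, method="normal_approx", B_small=30, seed=5)
        b = analyze_all(matrix, gm, method="normal_approx", B_small=30, seed=5)
        assert a.equals(b)

    def test_gene_order_does_not_change_pvalues(self, study):
        matrix, gm = study
        rev = GeneMap({g: gm[g] for g in reversed(list(gm))})
        a = analyze_all(matrix, gm, method="normal_approx", B_small=30, seed=5)
        b = analyze_all(matrix, rev, method="normal_approx", B_small=30, seed=5)
        merged = a.merge(b, on="gene_id", suffixes=("_a", "_b"))
        assert (merged["p_value_a"] == merged["p_value_b"]).all()

    def test_significance_count_matches_manual_filter(self, study):
        matrix, gm = study
        out = analyze_all(matrix, gm, method="normal_approx", B_small=30, seed=2)
        n_sig = int((out["p_value"] <= 0.05).sum())
        assert n_sig == len(out[out["p_value"] <= 0.05])

    def test_bh_column_monotone_and_bounded(self, study):
        matrix, gm = study
        out = analyze_all(matrix, gm, method="normal_approx", B_small=30, seed=2,
                          bh_adjust=True)
        ok = out.dropna(subset=["p_value"])
        assert (ok["p_adj_BH"] >= ok["p_value"] - 1e-12).all()
        assert (ok["p_adj_BH"] <= 1.0).all()

    def test_pvalues_in_unit_interval(self, study):
        matrix, gm = study
        out = analyze_all(matrix, gm, method="normal_approx", B_small=30, seed=3)
        p = out["p_value"].dropna()
        assert ((p > 0) & (p <= 1)).all()


class TestApproximationPanel:
    def test_panel_columns_and_ranges(self):
        matrix, _, gm = generate_ipmn_like_fixture(seed=10, n_subjects=20, n_case=10,
                                                   n_genes=15, assoc_fraction=0.3)
        panel = approximation_panel(matrix, gm, B_small_grid=(20, 50), B_ref=500, seed=6)
        assert list(panel["B_small"]) == [20, 50]
        assert ((panel["R2"] >= 0) & (panel["R2"] <= 1)).all()
        assert {"ks_pvalue", "mse", "pearson", "spearman"} <= set(panel.columns)
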