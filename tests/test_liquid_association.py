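import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from triwi import (
    InputError,
    adjust_pvalues,
    adjust_screen,
    bin_by_z,
    compute_pvalues,
    mla_score,
    normalize_matrix,
    permutation_pvalue,
    screen_all_triplets,
    significant_triplets,
    standardize,
)
from triwi.liquid_association import TripletScore
from .conftest import make_matrix


def worked_example():
    """9-sample, 3-bin construction with within-bin correlations (-1, 0, +1).

    With z = standardize(1..9) the bin means are (-1.0955, 0, +1.0955), so
    MLA = ((-1)(-1.0955) + 0 + (+1)(1.0955)) / 3 = 0.7303.
    """
    z = standardize(np.arange(1.0, 10.0))
    x = np.tile([1.0, 2.0, 3.0], 3)
    y = np.concatenate([[3.0, 2.0, 1.0], [1.0, 3.0, 1.0], [1.0, 2.0, 3.0]])
    return x, y, z


class TestBinByZ:
    def test_nine_samples_three_even_bins(self):
        z = np.array([5.0, 1, 9, 3, 7, 2, 8, 4, 6])
        spec = bin_by_z(z, M=3)
        assert spec.sizes == [3, 3, 3]
        assert sorted(z[spec.assignment == 0]) == [1, 2, 3]
        assert sorted(z[spec.assignment == 2]) == [7, 8, 9]

    def test_remainder_goes_to_lowest_bins(self):
        spec = bin_by_z(np.arange(10.0), M=3)
        assert spec.sizes == [4, 3, 3]

    def test_too_few_samples_rejected(self):
        with pytest.raises(InputError):
            bin_by_z(np.arange(8.0), M=3)

    def test_ties_broken_by_sample_index(self):
        z = np.zeros(9)
        spec = bin_by_z(z, M=3)
        assert list(spec.assignment) == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_upper_tercile_boundary_matches_study_range(self):
        # normal scores at n=103: the top tercile starts near
        # Phi^-1(2/3) = 0.431 — the study reports its high-Z range as
        # 0.42 to 2.34 on the same standardized scale
        from triwi import normal_score_transform

        z = standardize(normal_score_transform(np.arange(103.0)))
        spec = bin_by_z(z, M=3)
        upper = z[spec.assignment == 2]
        assert upper.min() == pytest.approx(0.43, abs=0.03)


class TestMlaScore:
    def test_identical_pair_gives_zero_for_even_bins(self):
        rng = np.random.default_rng(0)
        z = standardize(rng.normal(size=9))
        x = rng.normal(size=9)
        mla, bins = mla_score(x, x, z, bin_by_z(z, 3))
        assert all(b.rho == pytest.approx(1.0) for b in bins)
        assert mla == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_value(self):
        x, y, z = worked_example()
        mla, bins = mla_score(x, y, z, bin_by_z(z, 3))
        assert [b.rho for b in bins] == pytest.approx([-1.0, 0.0, 1.0], abs=1e-12)
        assert mla == pytest.approx(0.7303, abs=1e-4)

    def test_negating_z_negates_mla_and_pair_symmetry(self):
        rng = np.random.default_rng(1)
        x, y, z = rng.normal(size=(3, 30))
        z = standardize(z)
        mla, _ = mla_score(x, y, z, bin_by_z(z, 3))
        neg, _ = mla_score(x, y, -z, bin_by_z(-z, 3))
        assert neg == pytest.approx(-mla, abs=1e-12)
        swapped, _ = mla_score(y, x, z, bin_by_z(z, 3))
        assert swapped == pytest.approx(mla, abs=1e-15)

    def test_zero_variance_bin_contributes_zero(self, caplog):
        z = standardize(np.arange(1.0, 10.0))
        x = np.r_[np.ones(3), 1.0, 2, 3, 1, 2, 3]  # constant in lowest bin
        y = np.arange(9.0)
        with caplog.at_level("WARNING"):
            mla, bins = mla_score(x, y, z, bin_by_z(z, 3))
        assert bins[0].rho == 0.0
        assert "zero within-bin variance" in caplog.text

    def test_mla_bounded_by_mean_abs_bin_z(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x, y, z = rng.normal(size=(3, 31))
            spec = bin_by_z(z, 3)
            mla, bins = mla_score(x, y, z, spec)
            assert abs(mla) <= np.mean([abs(b.z_bar) for b in bins]) + 1e-12


class TestScreenAllTriplets:
    def test_triplet_counts(self):
        rng = np.random.default_rng(3)
        m3 = normalize_matrix(make_matrix(rng.normal(size=(3, 12))))
        assert screen_all_triplets(m3).n_total == 3
        m30 = normalize_matrix(make_matrix(rng.normal(size=(30, 12))))
        assert screen_all_triplets(m30).n_total == 30 * 29 * 28 // 2

    def test_matches_bruteforce_on_20_genes(self):
        rng = np.random.default_rng(4)
        nm = normalize_matrix(make_matrix(rng.normal(size=(20, 40))))
        screen = screen_all_triplets(nm, M=3)
        V = nm.to_array()
        genes = nm.gene_ids
        idx = {g: i for i, g in enumerate(genes)}
        for row in screen.table.sample(200, random_state=0).itertuples(index=False):
            zi = V[idx[row.z]]
            expected, _ = mla_score(V[idx[row.x]], V[idx[row.y]], zi, bin_by_z(zi, 3))
            assert row.mla == pytest.approx(expected, abs=1e-10)

    def test_top_k_truncation_keeps_largest(self):
        rng = np.random.default_rng(5)
        nm = normalize_matrix(make_matrix(rng.normal(size=(10, 30))))
        full = screen_all_triplets(nm)
        short = screen_all_triplets(nm, top_k=17)
        assert len(short.table) == 17
        np.testing.assert_allclose(
            short.table["mla"].abs().to_numpy(),
            full.table["mla"].abs().to_numpy()[:17],
        )

    def test_deterministic(self, random_matrix):
        nm = normalize_matrix(random_matrix)
        a = screen_all_triplets(nm).table
        b = screen_all_triplets(nm).table
        assert a.equals(b)


class TestPermutationPvalue:
    def test_add_one_convention_floor(self):
        # a planted extreme triplet beats all B permutations
        rng = np.random.default_rng(6)
        z = standardize(rng.normal(size=90))
        order = np.argsort(z)
        x = rng.normal(size=90)
        y = np.empty(90)
        y[order[:30]] = x[order[:30]]          # r=+1 low bin
        y[order[30:60]] = rng.normal(size=30)
        y[order[60:]] = -x[order[60:]]         # r=-1 high bin
        p = permutation_pvalue(x, y, z, M=3, B=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_reproducible_and_b_validated(self):
        rng = np.random.default_rng(7)
        x, y, z = rng.normal(size=(3, 40))
        assert permutation_pvalue(x, y, z, B=199, seed=5) == permutation_pvalue(
            x, y, z, B=199, seed=5
        )
        with pytest.raises(InputError):
            permutation_pvalue(x, y, z, B=50)


class TestAdjustPvalues:
    def test_bh_step_up_by_hand(self):
        out = adjust_pvalues([0.01, 0.02, 0.03], method="bh", m_total=3)
        np.testing.assert_allclose(out, [0.03, 0.03, 0.03])

    def test_single_p_unchanged_by_either_method(self):
        for method in ("bonferroni", "bh"):
            assert adjust_pvalues([0.001], method=method)[0] == pytest.approx(0.001)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=30))
    def test_bonferroni_dominates_bh(self, ps):
        bonf = adjust_pvalues(ps, "bonferroni")
        bh = adjust_pvalues(ps, "bh")
        assert np.all(bonf >= bh - 1e-15)

    def test_matches_statsmodels_when_family_is_list_length(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(1e-6, 1, size=100)
        np.testing.assert_allclose(
            adjust_pvalues(p, "bh"), multipletests(p, method="fdr_bh")[1]
        )
        np.testing.assert_allclose(
            adjust_pvalues(p, "bonferroni"), multipletests(p, method="bonferroni")[1]
        )

    def test_bh_monotone_on_sorted_input(self):
        rng = np.random.default_rng(9)
        p = np.sort(rng.uniform(size=50))
        adj = adjust_pvalues(p, "bh", m_total=200)
        assert np.all(np.diff(adj) >= -1e-15)

    def test_family_smaller_than_list_rejected(self):
        with pytest.raises(InputError):
            adjust_pvalues([0.1, 0.2], "bh", m_total=1)

    def test_invalid_p_rejected(self):
        with pytest.raises(InputError):
            adjust_pvalues([0.0, 0.5], "bh")


class TestSignificantTriplets:
    def _screened(self):
        rng = np.random.default_rng(10)
        nm = normalize_matrix(make_matrix(rng.normal(size=(6, 30))))
        screen = screen_all_triplets(nm)
        screen = compute_pvalues(screen, nm, B=99, seed=0)
        return adjust_screen(screen)

    def test_alpha_extremes(self):
        screen = self._screened()
        assert len(significant_triplets(screen, alpha=1.1, criterion="bh").table) == len(
            screen.table
        )
        assert significant_triplets(screen, alpha=1e-300, criterion="bh").table.empty

    def test_toy_threshold_enumeration(self):
        screen = self._screened()
        alpha = float(screen.table["p_bonferroni"].median())
        sig = significant_triplets(screen, alpha=alpha, criterion="bonferroni")
        expected = (screen.table["p_bonferroni"] < alpha).sum()
        assert len(sig.table) == expected

    def test_pvalue_columns_well_formed(self):
        screen = self._screened()
        t = screen.table
        for col in ("p_perm", "p_normal", "p_raw", "p_bonferroni", "p_bh"):
            assert ((t[col] > 0) & (t[col] <= 1)).all()
        assert (t["p_bonferroni"] >= t["p_raw"] - 1e-15).all()


class TestTripletScore:
    def test_canonical_pair_order_and_distinctness(self):
        t = TripletScore(z_gene="c", x_gene="b", y_gene="a", mla=0.1)
        assert (t.x_gene, t.y_gene) == ("a", "b")
        with pytest.raises(InputError):
            TripletScore(z_gene="a", x_gene="a", y_gene="b", mla=0.0)
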