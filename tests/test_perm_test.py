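"""Shape PCA reduction, R² statistics and permutation calibration."""

import numpy as np
import pytest

import morphancestry as ma
from morphancestry.perm_test import groups_from_regions


def gaussian_shapes(rng, n, L=6):
    return ma.CohortShapes([f"i{k}" for k in range(n)],
                           rng.normal(size=(n, L, 3)))


class TestShapePCA:
    def test_exact_low_rank_data_retains_rank_components(self, rng):
        n, L = 30, 10
        basis = rng.normal(size=(2, 3 * L))
        flat = rng.normal(size=(n, 2)) @ basis
        pca = ma.shape_pca(flat.reshape(n, L, 3), var_threshold=0.999)
        assert pca.m_retained == 2

    def test_scores_are_unit_variance(self, rng):
        pca = ma.shape_pca(gaussian_shapes(rng, 40), 0.96)
        assert np.allclose(pca.scores.std(axis=0, ddof=1), 1.0)

    def test_cumulative_variance_reaches_threshold(self, rng):
        pca = ma.shape_pca(gaussian_shapes(rng, 40), 0.96)
        assert pca.retained_fraction >= 0.96
        # minimality: one component fewer falls below the threshold
        below = pca.eigenvalues[:-1].sum() / pca.total_variance
        assert below < 0.96

    def test_reconstruction_error_matches_discarded_variance(self, rng):
        n, L = 25, 8
        coords = rng.normal(size=(n, L, 3))
        pca = ma.shape_pca(coords, var_threshold=0.8)
        flat = coords.reshape(n, -1) - pca.mean
        raw_scores = flat @ pca.loadings
        resid = flat - raw_scores @ pca.loadings.T
        err_frac = (resid ** 2).sum() / (flat ** 2).sum()
        assert err_frac == pytest.approx(1 - pca.retained_fraction, abs=1e-8)

    def test_threshold_validated(self, rng):
        with pytest.raises(ValueError):
            ma.shape_pca(gaussian_shapes(rng, 10), var_threshold=1.5)

    def test_needs_three_individuals(self, rng):
        with pytest.raises(ValueError):
            ma.shape_pca(gaussian_shapes(rng, 2))


class TestTotalR2:
    def test_first_score_column_closed_form(self, rng):
        pca = ma.shape_pca(gaussian_shapes(rng, 40), 0.96)
        x = pca.scores[:, [0]]
        ev_mode = ma.total_r2(x, pca, "eigenvalue")
        unit_mode = ma.total_r2(x, pca, "unit")
        assert ev_mode == pytest.approx(
            pca.eigenvalues[0] / pca.eigenvalues.sum(), abs=1e-10)
        assert unit_mode == pytest.approx(1 / pca.m_retained, abs=1e-10)

    def test_pure_noise_r2_matches_expectation(self, rng):
        # E[R2] for an independent predictor is 1/(n-1) per component
        n = 200
        pca = ma.shape_pca(gaussian_shapes(rng, n), 0.96)
        r2s = [ma.total_r2(rng.normal(size=(n, 1)), pca, "unit")
               for _ in range(200)]
        expected = 1 / (n - 1)
        assert np.mean(r2s) == pytest.approx(expected, rel=0.3)

    def test_zero_variance_predictor_rejected(self, rng):
        pca = ma.shape_pca(gaussian_shapes(rng, 20), 0.96)
        with pytest.raises(ValueError):
            ma.total_r2(np.ones((20, 1)), pca)

    def test_too_many_predictors_rejected(self, rng):
        pca = ma.shape_pca(gaussian_shapes(rng, 10), 0.96)
        with pytest.raises(ValueError):
            ma.total_r2(rng.normal(size=(10, 10)), pca)

    def test_eigenvalue_mode_invariant_to_normalization_round_trip(self, rng):
        """Normalizing scores to unit variance and back-weighting by
        eigenvalues reproduces the raw-score variance-explained fraction."""
        n, L = 50, 8
        coords = rng.normal(size=(n, L, 3))
        pca = ma.shape_pca(coords, 0.96)
        x = rng.normal(size=(n, 1))
        # independent computation from raw (un-normalized) scores
        flat = coords.reshape(n, -1) - coords.reshape(n, -1).mean(0)
        raw = flat @ pca.loadings
        xc = x[:, 0] - x.mean()
        ess = (xc @ (raw - raw.mean(0))) ** 2 / (xc @ xc)
        tss = ((raw - raw.mean(0)) ** 2).sum(axis=0)
        expected = (ess / tss * pca.eigenvalues).sum() / pca.eigenvalues.sum()
        assert ma.total_r2(x, pca, "eigenvalue") == pytest.approx(
            expected, abs=1e-10)


class TestPermutationTest:
    def test_maximal_statistic_gives_minimal_p(self, rng):
        pca = ma.shape_pca(gaussian_shapes(rng, 30), 0.96)
        res = ma.permutation_test(pca.scores[:, [0]], pca, B=99, seed=1)
        assert res.p_value == pytest.approx(1 / 100)

    def test_p_bounded_below_by_add_one_rule(self, rng):
        pca = ma.shape_pca(gaussian_shapes(rng, 20), 0.96)
        for B in (9, 99):
            res = ma.permutation_test(rng.normal(size=(20, 1)), pca,
                                      B=B, seed=0)
            assert 1 / (B + 1) <= res.p_value <= 1.0

    def test_agrees_with_full_enumeration_at_n6(self, rng):
        """Random-permutation p matches the exact p over all 720 row
        permutations within 3 Monte-Carlo standard errors."""
        pca = ma.shape_pca(gaussian_shapes(rng, 6), 0.96)
        x = rng.normal(size=(6, 1))
        exact = ma.exact_permutation_test(x, pca)
        B = 719
        res = ma.permutation_test(x, pca, B=B, seed=3)
        se = np.sqrt(exact * (1 - exact) / B)
        assert abs(res.p_value - exact) <= 3 * se + 1 / (B + 1)

    def test_determinism_given_seed(self, rng):
        pca = ma.shape_pca(gaussian_shapes(rng, 25), 0.96)
        x = rng.normal(size=(25, 2))
        a = ma.permutation_test(x, pca, B=200, seed=7)
        b = ma.permutation_test(x, pca, B=200, seed=7)
        assert a.p_value == b.p_value

    def test_row_and_residual_schemes_agree_in_distribution(self, rng):
        pca = ma.shape_pca(gaussian_shapes(rng, 40), 0.96)
        x = pca.scores[:, [1]] + rng.normal(scale=2, size=(40, 1))
        p_rows = ma.permutation_test(x, pca, B=500, seed=1,
                                     scheme="rows").p_value
        p_resid = ma.permutation_test(x, pca, B=500, seed=2,
                                      scheme="residual").p_value
        assert abs(p_rows - p_resid) < 0.1

    def test_monotone_in_effect_size(self):
        """Median p never increases as the injected association grows."""
        medians = []
        for strength in (0.0, 0.5, 2.0):
            ps = []
            for rep in range(20):
                rep_rng = np.random.default_rng(100 * rep + int(strength * 10))
                shapes = gaussian_shapes(rep_rng, 30)
                pca = ma.shape_pca(shapes, 0.96)
                x = strength * pca.scores[:, [0]] + rep_rng.normal(size=(30, 1))
                ps.append(ma.permutation_test(x, pca, B=99,
                                              seed=rep).p_value)
            medians.append(np.median(ps))
        assert medians[0] >= medians[1] >= medians[2]

    def test_small_n_warns(self, rng):
        pca = ma.shape_pca(gaussian_shapes(rng, 4), 0.96)
        with pytest.warns(UserWarning, match="n < 5"):
            ma.permutation_test(rng.normal(size=(4, 1)), pca, B=10, seed=0)


class TestSubgroupTests:
    def test_table_layout_matches_protocol(self, rng):
        n = 40
        labels = np.repeat(["North", "South", "East", "West"], 10)
        shapes = gaussian_shapes(rng, n, L=8)
        scores = rng.normal(size=(n, 5))
        table = ma.subgroup_tests(scores, shapes, labels,
                                  pc_list=[1, 2], B=50, seed=0)
        groups = groups_from_regions(("North", "South", "East", "West"))
        assert len(groups) == 11  # ALL + 6 pairs + 4 singles
        assert set(table["group"]) == {
            "ALL", "North-South", "North-East", "North-West", "South-East",
            "South-West", "East-West", "North", "South", "East", "West"}
        pivot = table.pivot(index="predictor_set", columns="group", values="p")
        assert pivot.shape == (2, 11)

    def test_pairwise_group_detects_mean_shift_on_pc_axis(self, rng):
        """Two regions differing along a PC-aligned shape axis: that PC is
        significant in their pairwise test, a noise PC is not."""
        hits_signal, hits_noise = 0, 0
        reps = 10
        for rep in range(reps):
            rep_rng = np.random.default_rng(rep)
            n = 60
            labels = np.repeat(["A", "B"], 30)
            direction = rep_rng.normal(size=18)
            offset = np.where(labels == "A", 1.0, -1.0)
            flat = (offset[:, None] * direction
                    + rep_rng.normal(size=(n, 18)))
            shapes = ma.CohortShapes([f"i{k}" for k in range(n)],
                                     flat.reshape(n, 6, 3))
            scores = np.column_stack([
                offset + rep_rng.normal(scale=0.5, size=n),
                rep_rng.normal(size=n)])
            table = ma.subgroup_tests(scores, shapes, labels,
                                      groups=[("A", "B")],
                                      pc_list=[1, 2], B=99, seed=rep)
            p1 = table[table.predictor_set == "PC1"].p.iloc[0]
            p2 = table[table.predictor_set == "PC2"].p.iloc[0]
            hits_signal += p1 < 0.05
            hits_noise += p2 < 0.05
        assert hits_signal >= 9
        assert hits_noise <= 3

    def test_tiny_subset_flagged_not_computed(self, rng):
        labels = np.array(["A"] * 3 + ["B"] * 20)
        shapes = gaussian_shapes(rng, 23)
        scores = rng.normal(size=(23, 2))
        table = ma.subgroup_tests(scores, shapes, labels,
                                  groups=[("A",), ("B",)], pc_list=[1],
                                  B=20, seed=0)
        flagged = table[table["group"] == "A"]
        assert (flagged["flag"] == "too-few").all()
        assert flagged["p"].isna().all()
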