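"""PLSR fitting, covariate/ancestry correction and effect extraction."""

import numpy as np
import pytest

import morphancestry as ma
from morphancestry.covariate_model import STANDARD_COVARIATES
from morphancestry.shape_align import gpa, symmetrize_cohort


def ols_coefficients(X, Y):
    """Normal-equations oracle on the standardized design."""
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    D = np.column_stack([np.ones(len(X)), Xs])
    beta = np.linalg.solve(D.T @ D, D.T @ (Y - Y.mean(0)))
    return beta[1:]


class TestFitPLSR:
    def test_noiseless_single_predictor_recovery(self, rng):
        x = rng.normal(size=(50, 1))
        b = rng.normal(size=(1, 12))
        model = ma.fit_plsr(x, x @ b)
        # coefficients act on standardized x
        assert np.allclose(model.coefficients,
                           b * x.std(ddof=1), atol=1e-10)

    def test_full_component_fit_equals_ols(self, rng):
        X = rng.normal(size=(60, 3))
        Y = X @ rng.normal(size=(3, 30)) + rng.normal(size=(60, 30))
        model = ma.fit_plsr(X, Y, n_components=3)
        assert np.abs(model.coefficients - ols_coefficients(X, Y)).max() < 1e-6

    def test_prediction_at_mean_is_mean(self, rng):
        X = rng.normal(size=(40, 2))
        Y = rng.normal(size=(40, 9))
        model = ma.fit_plsr(X, Y)
        assert np.allclose(model.predict(model.x_mean)[0], model.y_mean)

    def test_constant_predictor_rejected_by_name(self, rng):
        X = rng.normal(size=(30, 2))
        X[:, 1] = 5.0
        with pytest.raises(ValueError, match="camera"):
            ma.fit_plsr(X, rng.normal(size=(30, 6)),
                        predictor_names=["age", "camera"])

    def test_component_count_validated(self, rng):
        X = rng.normal(size=(30, 2))
        with pytest.raises(ValueError, match="n_components"):
            ma.fit_plsr(X, rng.normal(size=(30, 6)), n_components=3)

    def test_rank_deficient_design_reduces_with_warning(self, rng):
        X = rng.normal(size=(30, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        with pytest.warns(UserWarning, match="rank"):
            model = ma.fit_plsr(X, rng.normal(size=(30, 6)))
        assert model.n_components == 2


class TestCorrect:
    def test_independent_predictors_leave_shapes_unchanged(self, rng):
        # Y constant: nothing to explain, residuals + mean = original
        coords = np.broadcast_to(rng.normal(size=(5, 3)), (20, 5, 3)).copy()
        cohort = ma.CohortShapes([f"i{k}" for k in range(20)], coords)
        out = ma.correct(cohort, rng.normal(size=(20, 2)))
        assert np.allclose(out.shapes.coords, coords, atol=1e-10)

    def test_known_sex_effect_removed(self, tiny_cohort):
        sym = symmetrize_cohort(tiny_cohort.shapes, tiny_cohort.template)
        aligned = gpa(sym)
        cov = tiny_cohort.covariates
        cov.table["centroid_size"] = aligned.centroid_sizes
        X = cov.design_matrix(STANDARD_COVARIATES)
        out = ma.correct(aligned.shapes, X,
                         predictor_names=list(STANDARD_COVARIATES))
        sex = cov.table["sex"].to_numpy()
        male = out.shapes.coords[sex == 1].mean(axis=0)
        female = out.shapes.coords[sex == -1].mean(axis=0)
        before_gap = np.abs(
            aligned.shapes.coords[sex == 1].mean(axis=0)
            - aligned.shapes.coords[sex == -1].mean(axis=0)).max()
        assert np.abs(male - female).max() < before_gap
        # the residual male-female gap is pure sampling noise of the other
        # effects; it must be far below the injected sex field amplitude
        sex_field = tiny_cohort.true_covariate_effects["sex"]
        size = aligned.centroid_sizes.mean()
        assert np.abs(male - female).max() < 2 * np.abs(sex_field).max() / size

    def test_correcting_twice_is_idempotent(self, rng):
        coords = rng.normal(size=(30, 8, 3))
        X = rng.normal(size=(30, 3))
        cohort = ma.CohortShapes([f"i{k}" for k in range(30)], coords)
        once = ma.correct(cohort, X)
        twice = ma.correct(once.shapes, X)
        assert np.abs(twice.shapes.coords - once.shapes.coords).max() < 1e-8

    def test_grand_mean_preserved(self, rng):
        coords = rng.normal(size=(25, 6, 3))
        X = rng.normal(size=(25, 4))
        cohort = ma.CohortShapes([f"i{k}" for k in range(25)], coords)
        out = ma.correct(cohort, X)
        assert np.abs(out.shapes.coords.mean(0) - coords.mean(0)).max() < 1e-10

    def test_residuals_uncorrelated_with_predictors(self, rng):
        X = rng.normal(size=(100, 5))
        Y = X @ rng.normal(size=(5, 18)) + rng.normal(size=(100, 18))
        cohort = ma.CohortShapes([f"i{k}" for k in range(100)],
                                 Y.reshape(100, 6, 3))
        out = ma.correct(cohort, X)
        resid = out.shapes.coords.reshape(100, 18)
        for j in range(5):
            r = np.corrcoef(np.column_stack([X[:, [j]], resid]).T)[0, 1:]
            assert np.abs(r).max() < 1e-6


class TestAncestryCorrect:
    def _corrected(self, cohort):
        sym = symmetrize_cohort(cohort.shapes, cohort.template)
        aligned = gpa(sym)
        cov = cohort.covariates
        cov.table["centroid_size"] = aligned.centroid_sizes
        return ma.correct(aligned.shapes,
                          cov.design_matrix(STANDARD_COVARIATES))

    def test_zero_pcs_give_zero_effect(self, rng):
        coords = rng.normal(size=(20, 6, 3))
        cohort = ma.CohortShapes([f"i{k}" for k in range(20)], coords)
        corrected = ma.correct(cohort, rng.normal(size=(20, 2)))
        pcs = ma.GeneticPCs(corrected.shapes.ids, np.zeros((20, 4)))
        with pytest.warns(UserWarning, match="constant ancestry PCs"):
            out, effect = ma.ancestry_correct(corrected, pcs, k=4)
        assert np.array_equal(out.shapes.coords, corrected.shapes.coords)
        assert np.abs(effect.per_individual).max() == 0.0

    def test_recovers_injected_regional_deformation(self):
        cfg = ma.GeneratorConfig(n_per_region=40, n_landmarks=200, seed=21)
        cohort = ma.generate_cohort(cfg)
        corrected = self._corrected(cohort)
        labels = cohort.region_labels()
        _, effect = ma.ancestry_correct(corrected, cohort.pcs, k=4,
                                        labels=labels)
        rec = effect.per_region["South"].ravel()
        true = ma.true_effect_map(cohort, "South").ravel()
        r = np.corrcoef(rec, true)[0, 1]
        assert r > 0.9

    def test_default_protocol_uses_four_pcs(self, rng):
        coords = rng.normal(size=(30, 6, 3))
        cohort = ma.CohortShapes([f"i{k}" for k in range(30)], coords)
        corrected = ma.correct(cohort, rng.normal(size=(30, 2)))
        pcs = ma.GeneticPCs(corrected.shapes.ids, rng.normal(size=(30, 10)))
        out, _ = ma.ancestry_correct(corrected, pcs)
        assert out.model.n_components == 4
        assert out.model.predictor_names == ["PC1", "PC2", "PC3", "PC4"]

    def test_effect_means_respect_region_partition(self, tiny_cohort):
        corrected = self._corrected(tiny_cohort)
        labels = tiny_cohort.region_labels()
        _, effect = ma.ancestry_correct(corrected, tiny_cohort.pcs, k=4,
                                        labels=labels)
        for region in tiny_cohort.region_names:
            manual = effect.per_individual[labels == region].mean(axis=0)
            assert np.allclose(effect.per_region[region], manual)


class TestSinglePCEffect:
    def test_noise_pc_has_negligible_effect(self, rng):
        n = 120
        scores = rng.normal(size=(n, 4))
        Y = np.outer(scores[:, 0], rng.normal(size=18))  # only PC1 matters
        cohort = ma.CohortShapes([f"i{k}" for k in range(n)],
                                 Y.reshape(n, 6, 3))
        corrected = ma.correct(cohort, rng.normal(size=(n, 2)))
        pcs = ma.GeneticPCs(corrected.shapes.ids, scores)
        noise_f, _ = ma.single_pc_effect(corrected, pcs, exclude=3)
        signal_f, _ = ma.single_pc_effect(corrected, pcs, exclude=1)
        assert np.abs(noise_f).max() < 0.05 * np.abs(signal_f).max()

    def test_effects_add_up_for_orthogonalized_pcs(self, rng):
        n = 60
        raw = rng.normal(size=(n, 4))
        q, _ = np.linalg.qr(raw - raw.mean(0))  # exactly orthogonal in-sample
        scores = q
        Y = scores @ rng.normal(size=(4, 18)) + rng.normal(size=(n, 18))
        cohort = ma.CohortShapes([f"i{k}" for k in range(n)],
                                 Y.reshape(n, 6, 3))
        corrected = ma.correct(cohort, rng.normal(size=(n, 2)))
        pcs = ma.GeneticPCs(corrected.shapes.ids, scores)
        total = sum(ma.single_pc_effect(corrected, pcs, exclude=j)[0]
                    for j in range(1, 5))
        full, _ = ma.ancestry_correct(corrected, pcs, k=4)
        full_effect = corrected.shapes.coords - full.shapes.coords
        # each leave-one-out contrast carries the excluded PC's share once
        assert np.abs(total - full_effect).max() < 1e-8

    def test_cohort_mean_effect_vanishes(self, rng):
        n = 50
        scores = rng.normal(size=(n, 4))
        Y = scores @ rng.normal(size=(4, 18)) + rng.normal(size=(n, 18))
        cohort = ma.CohortShapes([f"i{k}" for k in range(n)],
                                 Y.reshape(n, 6, 3))
        corrected = ma.correct(cohort, rng.normal(size=(n, 2)))
        pcs = ma.GeneticPCs(corrected.shapes.ids, scores)
        _, mean_field = ma.single_pc_effect(corrected, pcs, exclude=2)
        assert np.abs(mean_field).max() < 1e-8

    def test_exclude_out_of_range_rejected(self, rng):
        coords = rng.normal(size=(20, 6, 3))
        cohort = ma.CohortShapes([f"i{k}" for k in range(20)], coords)
        corrected = ma.correct(cohort, rng.normal(size=(20, 2)))
        pcs = ma.GeneticPCs(corrected.shapes.ids, rng.normal(size=(20, 4)))
        with pytest.raises(ValueError, match="exclude"):
            ma.single_pc_effect(corrected, pcs, exclude=5)


class TestExaggerate:
    @pytest.mark.parametrize("factor", [0.0, 1.0, 4.0, 8.0])
    def test_linear_in_factor(self, rng, factor):
        base = rng.normal(size=(7, 3))
        effect = rng.normal(size=(7, 3))
        assert np.allclose(ma.exaggerate(base, effect, factor),
                           base + factor * effect)

    def test_nonfinite_rejected(self):
        base = np.zeros((3, 3))
        bad = np.full((3, 3), np.nan)
        with pytest.raises(ValueError):
            ma.exaggerate(base, bad, 4.0)
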