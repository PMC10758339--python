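"""Control-anchored confound regression: recovery, anchoring, fold hygiene."""

import numpy as np
import pytest

from anrisk.data import ACAN_TP1, HC, FeatureKind
from anrisk.deconfound import (
    apply_confound_model,
    deconfound_within_folds,
    fit_confound_model,
)
from anrisk.errors import EstimationError

from conftest import build_table


def linear_confound_table(n=40, slopes=(0.5, -0.2), rng=None):
    """Features that are exact linear functions of age (no noise)."""
    rng = rng or np.random.default_rng(0)
    ages = rng.uniform(12, 30, n)
    values = np.column_stack([2.0 + slopes[0] * ages, 5.0 + slopes[1] * ages])
    groups = [HC if i % 2 == 0 else ACAN_TP1 for i in range(n)]
    kinds = [FeatureKind.CORTICAL_THICKNESS, FeatureKind.CORTICAL_THICKNESS]
    return build_table(values, groups, ages=ages, kinds=kinds), ages


class TestFit:
    def test_exact_slope_recovery_on_noiseless_data(self):
        table, _ = linear_confound_table()
        model = fit_confound_model(table)
        for j, slope in enumerate((0.5, -0.2)):
            coefs = model.confounds_for(table.feature_names[j])
            assert coefs["age"] == pytest.approx(slope, abs=1e-8)

    def test_thickness_features_get_no_etiv_coefficient(self, two_group_table):
        model = fit_confound_model(two_group_table)
        thick = next(
            d.name
            for d in two_group_table.descriptors
            if d.kind == FeatureKind.CORTICAL_THICKNESS
        )
        vol = next(
            d.name for d in two_group_table.descriptors if d.kind != FeatureKind.CORTICAL_THICKNESS
        )
        assert set(model.confounds_for(thick)) == {"age"}
        assert set(model.confounds_for(vol)) == {"age", "etiv"}

    def test_with_bmi_mode_extends_both_sets(self, two_group_table):
        model = fit_confound_model(two_group_table, mode="with_bmi")
        thick = next(
            d.name
            for d in two_group_table.descriptors
            if d.kind == FeatureKind.CORTICAL_THICKNESS
        )
        assert set(model.confounds_for(thick)) == {"age", "bmi_sds"}

    def test_null_slopes_within_sampling_error(self, rng):
        n = 1000
        ages = rng.uniform(12, 30, n)
        values = rng.standard_normal((n, 6))
        table = build_table(values, [HC] * n, ages=ages)
        model = fit_confound_model(table)
        se = 1.0 / (np.sqrt(n) * ages.std())
        assert np.all(np.abs(model.coef[:, model.confound_names.index("age")]) < 4 * se)

    def test_too_few_reference_rows(self):
        table, _ = linear_confound_table(n=6)
        with pytest.raises(EstimationError):
            fit_confound_model(table, training_rows=np.arange(4))

    def test_estimation_ignores_patient_rows_bitwise(self, two_group_table):
        """Replacing every patient row with garbage leaves the model identical."""
        model1 = fit_confound_model(two_group_table)
        corrupted = two_group_table.copy()
        an = corrupted.group_mask(ACAN_TP1)
        corrupted.values[an] = 1e9
        model2 = fit_confound_model(corrupted)
        np.testing.assert_array_equal(model1.coef, model2.coef)
        np.testing.assert_array_equal(model1.intercept, model2.intercept)

    def test_serialization_round_trip(self, two_group_table, tmp_path):
        model = fit_confound_model(two_group_table)
        path = tmp_path / "model.json"
        model.to_json(path)
        from anrisk.deconfound import ConfoundModel

        back = ConfoundModel.from_json(path)
        np.testing.assert_allclose(back.coef, model.coef, atol=1e-12)
        assert back.confound_means == model.confound_means


class TestApply:
    def test_zero_slope_model_is_identity(self, two_group_table):
        model = fit_confound_model(two_group_table)
        model.coef[:] = 0.0
        out = apply_confound_model(model, two_group_table)
        np.testing.assert_array_equal(out.values, two_group_table.values)

    def test_noiseless_residuals_are_constant(self):
        table, _ = linear_confound_table()
        model = fit_confound_model(table)
        out = apply_confound_model(model, table)
        assert np.ptp(out.values, axis=0).max() < 1e-8

    def test_residual_orthogonality_on_training_controls(self):
        table, ages = linear_confound_table()
        model = fit_confound_model(table)
        out = apply_confound_model(model, table)
        hc = table.group_mask(HC)
        for j in range(2):
            resid = out.values[hc, j] - out.values[hc, j].mean()
            assert np.abs(resid @ (ages[hc] - ages[hc].mean())) < 1e-6

    def test_idempotent_after_refit(self, two_group_table):
        model = fit_confound_model(two_group_table)
        once = apply_confound_model(model, two_group_table)
        model2 = fit_confound_model(once)
        twice = apply_confound_model(model2, once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-8)

    def test_group_effect_orthogonal_to_confounds_preserved(self, rng):
        """A planted group-mean difference unrelated to any confound survives."""
        n = 200
        ages = rng.uniform(12, 30, n)
        groups = [HC] * 100 + [ACAN_TP1] * 100
        values = 0.3 * (ages - 21)[:, None] + rng.standard_normal((n, 4)) * 0.0
        values[100:] += 2.0
        table = build_table(values, groups, ages=ages)
        out = apply_confound_model(fit_confound_model(table), table)
        diff = out.values[100:].mean(axis=0) - out.values[:100].mean(axis=0)
        assert np.allclose(diff, 2.0, atol=1e-8)


class TestWithinFolds:
    def test_single_fold_reduces_to_fit_plus_apply(self, two_group_table):
        folds = np.zeros(two_group_table.n_scans, dtype=int)
        via_folds = deconfound_within_folds(two_group_table, folds)
        direct = apply_confound_model(
            fit_confound_model(two_group_table), two_group_table
        )
        np.testing.assert_array_equal(via_folds.values, direct.values)

    def test_test_row_cannot_influence_its_own_fold_model(self, two_group_table):
        """Perturbing a test row's features changes only that row's output."""
        folds = np.arange(two_group_table.n_scans) % 4
        out1 = deconfound_within_folds(two_group_table, folds)
        perturbed = two_group_table.copy()
        r = 0  # an HC row in fold 0
        perturbed.values[r] += 123.0
        out2 = deconfound_within_folds(perturbed, folds)
        same_fold_others = (folds == folds[r]) & (np.arange(len(folds)) != r)
        np.testing.assert_array_equal(
            out1.values[same_fold_others], out2.values[same_fold_others]
        )
        # the perturbed row changes by exactly its own perturbation
        np.testing.assert_allclose(out2.values[r] - out1.values[r], 123.0, atol=1e-9)

    def test_fold_without_controls_in_training(self):
        values = np.ones((6, 2))
        groups = [HC, HC, HC, ACAN_TP1, ACAN_TP1, ACAN_TP1]
        table = build_table(values, groups)
        folds = np.array([1, 1, 1, 0, 0, 0])  # fold 1 leaves no HC in training
        with pytest.raises(EstimationError):
            deconfound_within_folds(table, folds)
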