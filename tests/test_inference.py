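"""Permutation inference, deviance partitioning, outcome GLM."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from anrisk.cohort import GenerativeConfig, generate_cohort
from anrisk.data import ACAN_TP1, ACAN_TP2, HC, RECAN
from anrisk.errors import EstimationError
from anrisk.inference import (
    PermutationResult,
    deviance_explained,
    deviance_partition,
    frozen_config,
    outcome_glm,
    permutation_test_auc,
)
from anrisk.pipeline import PipelineConfig

FROZEN = frozen_config(
    PipelineConfig(inner_folds=3, inner_repeats=1, outer_folds=3, outer_repeats=1),
    n_components=8,
    C=1.0,
)


def newton_raphson_logistic_deviance(y, x):
    """Independent unpenalized Newton-Raphson logistic fit; returns deviance."""
    design = np.column_stack([np.ones(len(y)), x])
    beta = np.zeros(design.shape[1])
    for _ in range(100):
        eta = design @ beta
        mu = 1 / (1 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = design.T @ (y - mu)
        hess = (design * w[:, None]).T @ design
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    mu = 1 / (1 + np.exp(-(design @ beta)))
    return -2 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))


class TestDevianceExplained:
    def test_matches_independent_newton_raphson_on_hand_data(self):
        y = np.array([0, 0, 0, 1, 0, 1, 1, 1], dtype=float)
        x = np.array([0.2, 1.1, 0.8, 1.5, 1.3, 0.7, 1.9, 2.1])
        dev = newton_raphson_logistic_deviance(y, x)
        p = y.mean()
        null_dev = -2 * (y.sum() * np.log(p) + (len(y) - y.sum()) * np.log(1 - p))
        expected = 1 - dev / null_dev
        assert deviance_explained(y, x[:, None]) == pytest.approx(expected, abs=1e-8)

    def test_pure_noise_predictor_explains_nothing(self, rng):
        y = rng.integers(0, 2, 2000).astype(float)
        x = rng.standard_normal((2000, 1))
        assert deviance_explained(y, x) == pytest.approx(0.0, abs=0.01)

    def test_label_predictor_saturates(self, rng):
        y = rng.integers(0, 2, 300).astype(float)
        x = (2 * y - 1 + 0.001 * rng.standard_normal(300))[:, None]
        assert deviance_explained(y, x) >= 0.95

    def test_affine_rescaling_invariance(self, rng):
        y = rng.integers(0, 2, 200).astype(float)
        x = rng.standard_normal((200, 2))
        x[:, 0] += y
        d1 = deviance_explained(y, x)
        x2 = x.copy()
        x2[:, 0] = 1000.0 * x2[:, 0] - 7.0
        assert deviance_explained(y, x2) == pytest.approx(d1, abs=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(EstimationError):
            deviance_explained(np.ones(10), np.random.default_rng(0).standard_normal((10, 1)))


class TestDeviancePartition:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_additivity_identity(self, seed):
        """Exclusive components plus shared always sum to the joint deviance."""
        r = np.random.default_rng(seed)
        n = int(r.integers(30, 80))
        risk = r.standard_normal(n)
        conf = r.standard_normal((n, 2))
        y = (risk + conf[:, 0] + r.standard_normal(n) > 0).astype(float)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        part = deviance_partition(risk, conf, y)
        assert part.model_exclusive + part.shared == pytest.approx(part.d_model, abs=1e-10)
        assert part.confound_exclusive + part.shared == pytest.approx(
            part.d_confounds, abs=1e-10
        )
        assert part.model_exclusive + part.confound_exclusive + part.shared == (
            pytest.approx(part.d_joint, abs=1e-10)
        )

    def test_risk_identical_to_confound_has_no_exclusive_deviance(self, rng):
        y = rng.integers(0, 2, 200).astype(float)
        conf = rng.standard_normal((200, 2))
        conf[:, 0] += y
        risk = conf[:, 0].copy()
        part = deviance_partition(risk, conf, y)
        assert abs(part.model_exclusive) <= 0.005
        assert part.shared == pytest.approx(part.d_model, abs=0.01)

    def test_orthogonal_informative_predictors_share_nothing(self, rng):
        n = 4000
        risk = rng.standard_normal(n)
        conf = rng.standard_normal((n, 1))
        y = (0.5 * risk + 0.5 * conf[:, 0] + rng.standard_normal(n) > 0).astype(float)
        part = deviance_partition(risk, conf, y)
        # logistic deviance is not perfectly collapsible; near-zero sharing
        assert abs(part.shared) < 0.02
        assert part.model_exclusive == pytest.approx(part.d_model, abs=0.02)
        assert part.confound_exclusive == pytest.approx(part.d_confounds, abs=0.02)

    def test_permutation_p_values_detect_real_association(self, rng):
        n = 300
        risk = rng.standard_normal(n)
        conf = rng.standard_normal((n, 1))
        y = (1.5 * risk + rng.standard_normal(n) > 0).astype(float)
        part = deviance_partition(risk, conf, y, n_permutations=99, seed=4)
        assert part.p_values["model_exclusive"] == pytest.approx(0.01)
        assert part.p_values["confound_exclusive"] > 0.05


class TestPermutationTest:
    def test_degenerate_null_equal_to_observed_gives_p_one(self):
        res = PermutationResult("roc_auc", 0.6, np.full(10, 0.6), 10, 0)
        assert res.p_value == 1.0

    def test_p_value_floor(self):
        res = PermutationResult("roc_auc", 0.9, np.full(19, 0.5), 19, 0)
        assert res.p_value == pytest.approx(1 / 20)

    def test_strong_effect_reaches_minimum_p(self):
        """A clearly separable cohort saturates at the smallest attainable p."""
        cfg = GenerativeConfig(
            group_sizes={HC: 40, ACAN_TP1: 40, ACAN_TP2: 0, RECAN: 0},
            n_cortical=10,
            n_subcortical_gm=6,
            n_csf=4,
            gamma={HC: 0.0, ACAN_TP1: 3.0, ACAN_TP2: 0.0, RECAN: 0.0},
            seed=0,
        )
        table, _ = generate_cohort(cfg)
        res = permutation_test_auc(table, ACAN_TP1, FROZEN, n_permutations=19, seed=0)
        assert res["roc_auc"].p_value == pytest.approx(1 / 20)
        assert res["pr_auc"].p_value == pytest.approx(1 / 20)

    def test_null_data_gives_unremarkable_p(self):
        cfg = GenerativeConfig(
            group_sizes={HC: 30, ACAN_TP1: 30, ACAN_TP2: 0, RECAN: 0},
            n_cortical=8,
            n_subcortical_gm=4,
            n_csf=2,
            gamma={HC: 0.0, ACAN_TP1: 0.0, ACAN_TP2: 0.0, RECAN: 0.0},
            seed=1,
        )
        table, _ = generate_cohort(cfg)
        res = permutation_test_auc(table, ACAN_TP1, FROZEN, n_permutations=19, seed=1)
        assert res["roc_auc"].p_value > 0.1


class TestOutcomeGlm:
    def test_exact_linear_outcome(self, rng):
        risk = rng.standard_normal(50)
        outcome = 3.0 - 2.0 * risk
        fit = outcome_glm(outcome, risk)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.params["risk"] == pytest.approx(-2.0)
        assert fit.slope_p < 1e-20

    def test_covariate_is_reported(self, rng):
        risk = rng.standard_normal(80)
        bmi = rng.standard_normal(80)
        outcome = 5 - risk + 0.5 * bmi + rng.standard_normal(80)
        fit = outcome_glm(outcome, risk, covariate=bmi, covariate_name="bmi_sds")
        assert fit.covariate == "bmi_sds"
        assert set(fit.params) == {"intercept", "risk", "bmi_sds"}

    def test_constant_risk_rejected(self):
        with pytest.raises(EstimationError):
            outcome_glm(np.arange(10.0), np.ones(10))

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(EstimationError):
            outcome_glm(rng.standard_normal(4), rng.standard_normal(4))
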