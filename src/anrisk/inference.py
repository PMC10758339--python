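"""Statistical inference: permutation tests, deviance partitioning, outcome GLM.

Permutation significance of classification performance follows the
permute-everything scheme: for each permutation the group labels of the
task's rows are shuffled and the *full* pipeline — including the
control-anchored deconfounding on the permuted control set — is re-run, so
the null distribution reflects every data-dependent choice of the analysis.
A cheaper frozen-hyperparameter mode (singleton grids, no inner search) is
available and clearly approximate only in the sense that the grid search is
not part of the statistic; exchangeability is preserved because the frozen
hyperparameters are fixed a priori by the caller.

Confound assessment partitions the deviance explained by a logistic model of
group membership into components explained exclusively by the ML-based risk
score, exclusively by the confounds, and shared between them.  The shared
component may be negative (suppression).

The risk-score -> outcome analysis is an identity-link Gaussian GLM.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import statsmodels.api as sm

from ._seeds import rng_for, subseed
from .data import FeatureTable
from .errors import EstimationError
from .pipeline import CVPerformance, PipelineConfig, nested_cv_evaluate

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "permutation_test_auc",
    "deviance_explained",
    "DeviancePartition",
    "deviance_partition",
    "OutcomeFit",
    "outcome_glm",
]


# ---------------------------------------------------------------------------
# Permutation test for classification performance
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    """Observed statistic vs. a permutation null sample, with add-one p-value."""

    statistic: str
    observed: float
    null_sample: np.ndarray
    n_permutations: int
    seed: int

    @property
    def p_value(self) -> float:
        # add-one convention: never exactly zero, exact under exchangeability
        return float(
            (1 + np.sum(self.null_sample >= self.observed)) / (1 + self.n_permutations)
        )


def frozen_config(config: PipelineConfig, n_components: int, C: float) -> PipelineConfig:
    """A config with singleton grids: the inner search is skipped entirely."""
    return replace(
        config,
        pca_components_grid=(n_components,),
        pca_include_full=False,
        c_grid=(C,),
    )


def permutation_test_auc(
    table: FeatureTable,
    task,
    config: PipelineConfig,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    observed: CVPerformance | None = None,
) -> dict[str, PermutationResult]:
    """Permutation significance of nested-CV PR-AUC and ROC-AUC.

    Labels are permuted before everything; each permutation re-runs the whole
    nested-CV pipeline (deconfounding included, with the permuted 'control'
    set) with the same fold structure as the observed run.  Pass a config
    built by :func:`frozen_config` for the cheap frozen-hyperparameter mode.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if 1.0 / (1 + n_permutations) > alpha:
        logger.warning(
            "minimum attainable p-value %.4f exceeds alpha=%.3f; increase n_permutations",
            1.0 / (1 + n_permutations),
            alpha,
        )
    if observed is None:
        observed = nested_cv_evaluate(table, task, config)

    sub = table.subset(table.group_mask(task if isinstance(task, str) else task[0], "HC"))
    groups = sub.groups
    rng = rng_for(seed, "auc-permutations")
    null_roc = np.empty(n_permutations)
    null_pr = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(sub.n_scans)
        permuted = sub.copy()
        for rec, g in zip(permuted.records, groups[perm]):
            rec.group = g
        cv = nested_cv_evaluate(permuted, task, config)
        null_roc[b] = cv.roc_auc_mean
        null_pr[b] = cv.pr_auc_mean

    return {
        "roc_auc": PermutationResult(
            "roc_auc", observed.roc_auc_mean, null_roc, n_permutations, seed
        ),
        "pr_auc": PermutationResult(
            "pr_auc", observed.pr_auc_mean, null_pr, n_permutations, seed
        ),
    }


# ---------------------------------------------------------------------------
# Deviance explained / partitioned
# ---------------------------------------------------------------------------

_SEP_PENALTY = 1e-6


def _ridge_logistic_deviance(y: np.ndarray, design: np.ndarray, penalty: float) -> float:
    """Newton iterations for L2-penalized logistic regression; returns the
    (unpenalized) deviance at the penalized optimum.  Intercept unpenalized."""
    n, k = design.shape
    beta = np.zeros(k)
    pen = penalty * np.ones(k)
    pen[0] = 0.0
    eps = 1e-12

    def objective(b: np.ndarray) -> float:
        eta = np.clip(design @ b, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        nll = -np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps))
        return float(nll + 0.5 * np.sum(pen * b**2))

    obj = objective(beta)
    for _ in range(200):
        eta = np.clip(design @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        grad = design.T @ (y - mu) - pen * beta
        hess = (design * w[:, None]).T @ design + np.diag(pen + 1e-10)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # damped Newton: halve the step until the penalized objective improves
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            cand_obj = objective(cand)
            if cand_obj <= obj + 1e-12:
                break
            t *= 0.5
        else:
            break
        moved = np.max(np.abs(t * step))
        beta, obj = cand, cand_obj
        if moved < 1e-10:
            break
    eta = np.clip(design @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    return float(-2.0 * np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))


def _null_deviance(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    n1 = y.sum()
    n0 = len(y) - n1
    return float(-2.0 * (n1 * np.log(p) + n0 * np.log(1 - p)))


def deviance_explained(labels, predictors) -> float:
    """Proportion of deviance explained by a logistic model of the labels.

    ``1 - deviance(model) / deviance(intercept-only)``.  Fits by IRLS
    (statsmodels GLM); on perfect separation or non-convergence a small L2
    penalty (1e-6) is used instead and a warning logged.  Predictor columns
    are standardized internally, making the result invariant to affine
    rescaling of any column.
    """
    y = np.asarray(labels, dtype=float).ravel()
    x = np.atleast_2d(np.asarray(predictors, dtype=float))
    if x.shape[0] != len(y):
        x = x.T
    if x.shape[0] != len(y):
        raise ValueError("predictors must have one row per label")
    if len(np.unique(y)) < 2:
        raise EstimationError("both classes must be present")

    # standardize (constant columns left as zeros -> no contribution)
    m = x.mean(axis=0)
    s = x.std(axis=0)
    s_safe = np.where(s == 0, 1.0, s)
    xs = (x - m) / s_safe
    design = np.column_stack([np.ones(len(y)), xs])

    d0 = _null_deviance(y)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=200)
        dev = float(res.deviance)
        # IRLS can "converge" to nonsense on singular or separated designs
        if not np.isfinite(dev) or not res.converged or dev < 1e-8 or dev > d0 + 1e-6:
            raise EstimationError("non-converged, singular, or separated fit")
    except Exception:
        logger.warning("logistic fit unstable (possible separation); ridge fallback")
        dev = _ridge_logistic_deviance(y, design, _SEP_PENALTY)
    return 1.0 - dev / d0


@dataclass
class DeviancePartition:
    """Shared/exclusive deviance-explained components for group membership.

    ``model_exclusive + shared`` equals the deviance explained by the risk
    score alone, ``confound_exclusive + shared`` that of the confounds alone,
    and all three sum to the joint model's deviance explained (algebraic
    identity).  ``shared`` may be negative (suppression).
    """

    model_exclusive: float
    confound_exclusive: float
    shared: float
    d_model: float
    d_confounds: float
    d_joint: float
    confound_set: list[str] = field(default_factory=list)
    p_values: dict[str, float] = field(default_factory=dict)


def deviance_partition(
    risk,
    confounds,
    labels,
    confound_names: list[str] | None = None,
    n_permutations: int = 0,
    seed: int = 0,
) -> DeviancePartition:
    """Partition deviance explained for group membership into risk-score and
    confound components.

    ``shared = D(risk) + D(confounds) - D(risk, confounds)``; exclusives are
    the joint minus the other predictor set.  Component p-values (optional)
    come from permutation nulls: the risk vector is permuted across subjects
    for the model-related components (preserving the confound-label
    relation), the confound rows jointly for the confound-exclusive one.
    """
    risk = np.asarray(risk, dtype=float).ravel()
    conf = np.atleast_2d(np.asarray(confounds, dtype=float))
    if conf.shape[0] != len(risk):
        conf = conf.T
    y = np.asarray(labels, dtype=float).ravel()

    d_r = deviance_explained(y, risk[:, None])
    d_c = deviance_explained(y, conf)
    d_rc = deviance_explained(y, np.column_stack([risk, conf]))

    part = DeviancePartition(
        model_exclusive=d_rc - d_c,
        confound_exclusive=d_rc - d_r,
        shared=d_r + d_c - d_rc,
        d_model=d_r,
        d_confounds=d_c,
        d_joint=d_rc,
        confound_set=list(confound_names or []),
    )

    if n_permutations > 0:
        rng = rng_for(seed, "deviance-permutations")
        null_excl = np.empty(n_permutations)
        null_shared = np.empty(n_permutations)
        null_conf_excl = np.empty(n_permutations)
        for b in range(n_permutations):
            pr = rng.permutation(len(risk))
            d_r_b = deviance_explained(y, risk[pr, None])
            d_rc_b = deviance_explained(y, np.column_stack([risk[pr], conf]))
            null_excl[b] = d_rc_b - d_c
            null_shared[b] = d_r_b + d_c - d_rc_b
            pc = rng.permutation(len(risk))
            d_c_b = deviance_explained(y, conf[pc])
            d_rc_c = deviance_explained(y, np.column_stack([risk, conf[pc]]))
            null_conf_excl[b] = d_rc_c - d_r
        part.p_values = {
            "model_exclusive": float(
                (1 + np.sum(null_excl >= part.model_exclusive)) / (1 + n_permutations)
            ),
            "shared": float(
                (1 + np.sum(null_shared >= part.shared)) / (1 + n_permutations)
            ),
            "confound_exclusive": float(
                (1 + np.sum(null_conf_excl >= part.confound_exclusive))
                / (1 + n_permutations)
            ),
        }
    return part


# ---------------------------------------------------------------------------
# Risk score -> outcome GLM
# ---------------------------------------------------------------------------


@dataclass
class OutcomeFit:
    """Gaussian identity-link GLM of an outcome score on the ML-based risk score."""

    params: dict[str, float]
    bse: dict[str, float]
    slope_p: float
    slope_ci: tuple[float, float]
    r_squared: float
    n: int
    covariate: str | None = None


def outcome_glm(outcome, risk, covariate=None, covariate_name: str | None = None) -> OutcomeFit:
    """Fit ``outcome ~ risk (+ covariate)`` by OLS (= Gaussian identity GLM).

    The slope p-value is the two-sided t-test on the risk coefficient;
    R-squared is the squared multiple correlation of the fitted model.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    r = np.asarray(risk, dtype=float).ravel()
    if len(y) != len(r):
        raise ValueError("outcome and risk must have equal length")
    if np.std(r) == 0:
        raise EstimationError("risk vector is constant; slope is not identifiable")
    cols = [np.ones(len(y)), r]
    names = ["intercept", "risk"]
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float).ravel()
        cols.append(cov)
        names.append(covariate_name or "covariate")
    design = np.column_stack(cols)
    if len(y) < design.shape[1] + 3:
        raise EstimationError("need at least 3 more rows than parameters")
    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=0.05)
    return OutcomeFit(
        params=dict(zip(names, map(float, res.params))),
        bse=dict(zip(names, map(float, res.bse))),
        slope_p=float(res.pvalues[1]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        r_squared=float(res.rsquared),
        n=len(y),
        covariate=covariate_name if covariate is not None else None,
    )
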