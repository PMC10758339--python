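"""Classification pipeline: deconfounding, PCA, class-weighted linear SVM.

The pipeline mirrors the three-step design of the analysis it replicates:

1. control-anchored confound regression (:mod:`anrisk.deconfound`), fitted
   on the healthy-control rows of the training data only;
2. per-feature standardization (train-fitted z-scoring) followed by PCA for
   dimensionality reduction;
3. a linear L2-regularized support-vector classifier whose continuous
   decision value is the *ML-based risk score* (higher = more AN-like),
   with misclassification costs weighted by the inverse of each group's
   frequency.

The number of PCA components and the SVM inverse-penalty C are optimized
jointly by repeated stratified k-fold grid search maximizing mean PR-AUC.
Generalization performance is estimated by nested cross-validation: the
entire pipeline, deconfounding included, is re-fitted inside every outer
training set and evaluated on the untouched outer test fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import LinearSVC

from ._seeds import subseed
from .data import HC, FeatureTable
from .deconfound import ConfoundModel, apply_confound_model, fit_confound_model
from .errors import EstimationError, FoldError, SchemaError
from .metrics import pr_auc, roc_auc

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "FittedPipeline",
    "CVPerformance",
    "TransferPerformance",
    "fit_pipeline",
    "risk_scores",
    "nested_cv_evaluate",
    "transfer_classify",
]


@dataclass
class PipelineConfig:
    """Hyperparameter grids and cross-validation layout.

    Defaults follow the replicated design: 10-times-repeated stratified
    10-fold CV for both the inner (grid search) and outer (performance
    estimation) loops, PR-AUC as the selection metric, and grids spanning
    under- to over-parameterized models.  ``pca_include_full`` appends
    ``min(n, p)`` to the component grid, making PCA lossless at the top end.
    Tests and quick runs use reduced instances.
    """

    pca_components_grid: tuple[int, ...] = (5, 10, 20, 40, 80)
    pca_include_full: bool = True
    c_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)
    inner_folds: int = 10
    inner_repeats: int = 10
    outer_folds: int = 10
    outer_repeats: int = 10
    deconfound_mode: str = "standard"
    standardize: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not self.pca_components_grid or not self.c_grid:
            raise ValueError("hyperparameter grids must be nonempty")
        if min(self.inner_folds, self.outer_folds) < 2:
            raise ValueError("folds must be >= 2")
        if any(c <= 0 for c in self.c_grid):
            raise ValueError("C values must be positive")


@dataclass
class FittedPipeline:
    """A fully fitted pipeline; the risk score is a deterministic affine
    function of the (deconfounded, standardized) input, oriented so higher
    scores are more AN-like."""

    confound_model: ConfoundModel
    feature_names: list[str]
    standardize: bool
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    pca_mean: np.ndarray
    pca_components: np.ndarray  # (k, p)
    coef: np.ndarray  # (k,) classifier weights in PCA space
    intercept: float
    n_components: int
    C: float
    positive_group: str
    training_scan_ids: list[str]
    training_subject_ids: list[str]
    training_scores: np.ndarray
    grid_results: list[dict] = field(default_factory=list)

    @property
    def feature_weights(self) -> np.ndarray:
        """Risk-score gradient in raw (pre-deconfounding) feature space."""
        w = self.pca_components.T @ self.coef
        return w / self.scaler_scale

    def _score_deconfounded(self, xd: np.ndarray) -> np.ndarray:
        z = (xd - self.scaler_mean) / self.scaler_scale
        t = (z - self.pca_mean) @ self.pca_components.T
        return t @ self.coef + self.intercept


def _task_rows(table: FeatureTable, task) -> tuple[FeatureTable, np.ndarray, str]:
    """Restrict a table to an (AN group, HC) task; returns (subtable, y, an_group)."""
    if isinstance(task, (tuple, list)):
        an_group = task[0]
    else:
        an_group = task
    sub = table.subset(table.group_mask(an_group, HC))
    y = (sub.groups == an_group).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise EstimationError(f"both {an_group} and {HC} rows are required")
    return sub, y, an_group


def _svc(C: float) -> LinearSVC:
    # primal squared-hinge solver: deterministic, no internal randomness
    return LinearSVC(C=C, class_weight="balanced", dual=False, tol=1e-5, max_iter=20000)


def _grid_search(
    x: np.ndarray, y: np.ndarray, config: PipelineConfig, seed: int
) -> tuple[int, float, list[dict]]:
    """Repeated stratified CV over the joint (components, C) grid.

    Returns the winning combination by mean PR-AUC, ties broken toward fewer
    components, then stronger regularization (smaller C).
    """
    n, p = x.shape
    min_train = n - int(np.ceil(n / config.inner_folds))
    k_cap = min(min_train, p)
    ks = sorted({k for k in config.pca_components_grid if k <= k_cap})
    if config.pca_include_full:
        ks = sorted(set(ks) | {k_cap})
    dropped = [k for k in config.pca_components_grid if k > k_cap]
    if dropped:
        logger.warning("pruned infeasible PCA component counts %s (cap %d)", dropped, k_cap)
    if not ks:
        raise EstimationError("no feasible PCA component count in the grid")
    cs = list(config.c_grid)

    if len(ks) == 1 and len(cs) == 1:
        return ks[0], cs[0], []  # nothing to search

    cv = RepeatedStratifiedKFold(
        n_splits=config.inner_folds, n_repeats=config.inner_repeats, random_state=seed
    )
    k_max = max(ks)
    scores = np.zeros((len(ks), len(cs)))
    n_splits = 0
    for tr, va in cv.split(x, y):
        n_splits += 1
        xtr, xva = x[tr], x[va]
        if config.standardize:
            m = xtr.mean(axis=0)
            s = xtr.std(axis=0)
            s[s == 0] = 1.0
            xtr, xva = (xtr - m) / s, (xva - m) / s
        pca = PCA(n_components=min(k_max, len(tr), x.shape[1]), svd_solver="full")
        ttr = pca.fit_transform(xtr)
        tva = pca.transform(xva)
        for i, k in enumerate(ks):
            kk = min(k, ttr.shape[1])
            for j, c in enumerate(cs):
                clf = _svc(c).fit(ttr[:, :kk], y[tr])
                scores[i, j] += pr_auc(clf.decision_function(tva[:, :kk]), y[va])
    scores /= n_splits

    best = max(
        ((scores[i, j], -ks[i], -cs[j], i, j) for i in range(len(ks)) for j in range(len(cs))),
        key=lambda t: (t[0], t[1], t[2]),
    )
    grid = [
        {"n_components": ks[i], "C": cs[j], "mean_pr_auc": float(scores[i, j])}
        for i in range(len(ks))
        for j in range(len(cs))
    ]
    return ks[best[3]], cs[best[4]], grid


def fit_pipeline(table: FeatureTable, task, config: PipelineConfig) -> FittedPipeline:
    """Fit the full pipeline on the supplied rows.

    Deconfounding is fitted on the healthy-control rows of the supplied data
    only; the hyperparameter grid is searched by repeated stratified inner CV
    maximizing mean PR-AUC; the winning pipeline is refitted on all supplied
    rows.
    """
    config.validate()
    sub, y, an_group = _task_rows(table, task)

    cmodel = fit_confound_model(sub, mode=config.deconfound_mode)
    x = apply_confound_model(cmodel, sub).values

    k_best, c_best, grid = _grid_search(x, y, config, subseed(config.seed, "inner-cv"))

    if config.standardize:
        m = x.mean(axis=0)
        s = x.std(axis=0)
        s[s == 0] = 1.0
    else:
        m = np.zeros(x.shape[1])
        s = np.ones(x.shape[1])
    z = (x - m) / s
    k_fit = min(k_best, z.shape[0], z.shape[1])
    pca = PCA(n_components=k_fit, svd_solver="full").fit(z)
    t = pca.transform(z)
    clf = _svc(c_best).fit(t, y)

    model = FittedPipeline(
        confound_model=cmodel,
        feature_names=sub.feature_names,
        standardize=config.standardize,
        scaler_mean=m,
        scaler_scale=s,
        pca_mean=pca.mean_,
        pca_components=pca.components_,
        coef=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        n_components=k_fit,
        C=c_best,
        positive_group=an_group,
        training_scan_ids=sub.scan_ids,
        training_subject_ids=sub.subject_ids,
        training_scores=np.empty(0),
        grid_results=grid,
    )
    model.training_scores = model._score_deconfounded(x)
    return model


def risk_scores(model: FittedPipeline, table: FeatureTable) -> np.ndarray:
    """Continuous ML-based risk scores for the rows of ``table``."""
    table.assert_same_features(model.feature_names)
    xd = apply_confound_model(model.confound_model, table).values
    return model._score_deconfounded(xd)


@dataclass
class CVPerformance:
    """Nested-CV performance: per-outer-fold metrics and out-of-fold scores."""

    task: str
    roc_aucs: np.ndarray  # (repeats * folds,)
    pr_aucs: np.ndarray
    chosen_params: list[dict]
    scan_ids: list[str]
    oof_scores: np.ndarray  # (n_rows, repeats), each scan scored once per repeat
    labels: np.ndarray
    outer_folds: int
    outer_repeats: int
    fold_assignments: np.ndarray | None = None  # (n_rows, repeats) outer-fold index

    @property
    def roc_auc_mean(self) -> float:
        return float(self.roc_aucs.mean())

    @property
    def roc_auc_sd(self) -> float:
        return float(self.roc_aucs.std(ddof=1)) if len(self.roc_aucs) > 1 else 0.0

    @property
    def pr_auc_mean(self) -> float:
        return float(self.pr_aucs.mean())

    @property
    def pr_auc_sd(self) -> float:
        return float(self.pr_aucs.std(ddof=1)) if len(self.pr_aucs) > 1 else 0.0

    @property
    def oof_mean_scores(self) -> np.ndarray:
        """Out-of-fold risk score per scan, averaged over outer repeats."""
        return self.oof_scores.mean(axis=1)

    def summary(self) -> dict:
        return {
            "task": self.task,
            "roc_auc_mean": self.roc_auc_mean,
            "roc_auc_sd": self.roc_auc_sd,
            "pr_auc_mean": self.pr_auc_mean,
            "pr_auc_sd": self.pr_auc_sd,
            "outer_folds": self.outer_folds,
            "outer_repeats": self.outer_repeats,
            "n_rows": len(self.scan_ids),
        }


def nested_cv_evaluate(table: FeatureTable, task, config: PipelineConfig) -> CVPerformance:
    """Nested cross-validated performance estimate for one task.

    Outer repeated stratified folds; the entire pipeline (control-anchored
    deconfounding, standardization, PCA, inner grid search) runs inside each
    outer training set; ROC-AUC and PR-AUC are computed on the untouched
    outer test rows.
    """
    config.validate()
    sub, y, an_group = _task_rows(table, task)
    if min(np.bincount(y)) < config.outer_folds:
        raise FoldError(
            f"smallest class has {min(np.bincount(y))} rows, fewer than "
            f"{config.outer_folds} outer folds"
        )
    cv = RepeatedStratifiedKFold(
        n_splits=config.outer_folds,
        n_repeats=config.outer_repeats,
        random_state=subseed(config.seed, "outer-cv"),
    )
    rocs, prs, chosen = [], [], []
    oof = np.full((sub.n_scans, config.outer_repeats), np.nan)
    fold_of = np.full((sub.n_scans, config.outer_repeats), -1, dtype=int)
    for split_idx, (tr, te) in enumerate(cv.split(sub.values, y)):
        rep = split_idx // config.outer_folds
        fold_config = replace(config, seed=subseed(config.seed, "outer-fold", split_idx))
        model = fit_pipeline(sub.subset(tr), an_group, fold_config)
        scores = risk_scores(model, sub.subset(te))
        rocs.append(roc_auc(scores, y[te]))
        prs.append(pr_auc(scores, y[te]))
        chosen.append({"n_components": model.n_components, "C": model.C})
        oof[te, rep] = scores
        fold_of[te, rep] = split_idx % config.outer_folds
    assert not np.isnan(oof).any()
    return CVPerformance(
        task=an_group,
        roc_aucs=np.array(rocs),
        pr_aucs=np.array(prs),
        chosen_params=chosen,
        scan_ids=sub.scan_ids,
        oof_scores=oof,
        labels=y,
        outer_folds=config.outer_folds,
        outer_repeats=config.outer_repeats,
        fold_assignments=fold_of,
    )


@dataclass
class TransferPerformance:
    """Performance of a trained model applied to a different task."""

    source_task: str
    target_task: str
    roc_auc: float
    pr_auc: float
    n_test: int
    n_excluded: int


def transfer_classify(
    model: FittedPipeline, table: FeatureTable, target_task
) -> TransferPerformance:
    """Apply a trained model to another classification task.

    Rows whose subject already occurred in the model's training data are
    removed before scoring, so no scans of the same participant (taken at
    different timepoints) appear in both training and test sets.
    """
    sub, y, an_group = _task_rows(table, target_task)
    trained = set(model.training_subject_ids)
    keep = np.array([sid not in trained for sid in sub.subject_ids])
    if not keep.any() or len(set(y[keep])) < 2:
        raise EstimationError(
            "no usable test rows remain after excluding subjects seen in training"
        )
    scores = risk_scores(model, sub.subset(keep))
    return TransferPerformance(
        source_task=model.positive_group,
        target_task=an_group,
        roc_auc=roc_auc(scores, y[keep]),
        pr_auc=pr_auc(scores, y[keep]),
        n_test=int(keep.sum()),
        n_excluded=int((~keep).sum()),
    )
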