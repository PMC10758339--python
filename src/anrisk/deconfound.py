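"""Control-anchored, cross-validated confound regression.

Linear confound effects (age for all features; head size, eTIV, additionally
for volumetric features; optionally nutritional status, BMI-SDS, for all)
are estimated by ordinary least squares *exclusively on healthy-control
training rows*, so that disease-related effects are never absorbed into the
confound model, and then subtracted from every row — patients and controls,
training and test alike.  Confounds are centered at the training-control
means, so the adjustment shifts no group systematically except through the
fitted slopes.

Inside cross-validation the model is re-fitted per fold on the controls of
that fold's training part only ("cross-validated confound regression"), so a
test row never influences its own deconfounding.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import HC, FeatureKind, FeatureTable
from .errors import EstimationError, SchemaError

logger = logging.getLogger(__name__)

__all__ = ["ConfoundModel", "fit_confound_model", "apply_confound_model", "deconfound_within_folds"]

#: feature kind -> confound names, per deconfounding mode
CONFOUND_MAP = {
    "standard": {
        FeatureKind.CORTICAL_THICKNESS: ("age",),
        FeatureKind.SUBCORTICAL_GM_VOLUME: ("age", "etiv"),
        FeatureKind.CSF_VOLUME: ("age", "etiv"),
    },
    "with_bmi": {
        FeatureKind.CORTICAL_THICKNESS: ("age", "bmi_sds"),
        FeatureKind.SUBCORTICAL_GM_VOLUME: ("age", "etiv", "bmi_sds"),
        FeatureKind.CSF_VOLUME: ("age", "etiv", "bmi_sds"),
    },
}

_COND_THRESHOLD = 1e8
_RIDGE = 1e-8


@dataclass
class ConfoundModel:
    """Per-feature linear confound coefficients anchored on a reference group."""

    feature_names: list[str]
    feature_kinds: list[str]
    mode: str
    confound_names: list[str]  # all confounds used by any feature, in order
    coef: np.ndarray  # (p, n_confounds); structural zeros where unmapped
    intercept: np.ndarray  # (p,)
    confound_means: dict[str, float]  # training-HC means used for centering
    reference_group: str = HC

    def confounds_for(self, feature: str) -> dict[str, float]:
        """Mapped confound coefficients for one feature (structural zeros omitted)."""
        j = self.feature_names.index(feature)
        mapped = CONFOUND_MAP[self.mode][self.feature_kinds[j]]
        return {c: float(self.coef[j, self.confound_names.index(c)]) for c in mapped}

    # -- audit serialization --------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mode": self.mode,
            "reference_group": self.reference_group,
            "confound_means": self.confound_means,
            "features": [
                {
                    "name": n,
                    "kind": k,
                    "intercept": float(self.intercept[j]),
                    "coefficients": self.confounds_for(n),
                }
                for j, (n, k) in enumerate(zip(self.feature_names, self.feature_kinds))
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConfoundModel":
        payload = json.loads(Path(path).read_text())
        names = [f["name"] for f in payload["features"]]
        kinds = [f["kind"] for f in payload["features"]]
        confound_names = sorted({c for f in payload["features"] for c in f["coefficients"]})
        coef = np.zeros((len(names), len(confound_names)))
        for j, f in enumerate(payload["features"]):
            for c, v in f["coefficients"].items():
                coef[j, confound_names.index(c)] = v
        return cls(
            feature_names=names,
            feature_kinds=kinds,
            mode=payload["mode"],
            confound_names=confound_names,
            coef=coef,
            intercept=np.array([f["intercept"] for f in payload["features"]]),
            confound_means=payload["confound_means"],
            reference_group=payload["reference_group"],
        )


def _confound_matrix(table: FeatureTable, names: list[str]) -> np.ndarray:
    return np.column_stack([table.metadata(c) for c in names])


def fit_confound_model(
    table: FeatureTable,
    training_rows: np.ndarray | None = None,
    mode: str = "standard",
    reference_group: str = HC,
) -> ConfoundModel:
    """OLS confound fit on reference-group members of ``training_rows`` only.

    Non-reference training rows are ignored entirely: their feature values
    cannot influence the fitted model.  Raises
    :class:`~anrisk.errors.EstimationError` if fewer reference rows than
    ``max confound count + 2`` are available.  Near-collinear confounds
    (condition number above 1e8) trigger a logged ridge fallback (penalty
    1e-8 on the normal equations).
    """
    if mode not in CONFOUND_MAP:
        raise ValueError(f"unknown mode {mode!r}; expected one of {sorted(CONFOUND_MAP)}")
    if training_rows is None:
        training_rows = np.arange(table.n_scans)
    train = table.subset(training_rows)
    ref = train.subset(train.group_mask(reference_group))

    kind_map = CONFOUND_MAP[mode]
    confound_names = sorted({c for confs in kind_map.values() for c in confs})
    max_k = max(len(v) for v in kind_map.values())
    if ref.n_scans < max_k + 2:
        raise EstimationError(
            f"need at least {max_k + 2} {reference_group} training rows, got {ref.n_scans}"
        )

    means = {c: float(ref.metadata(c).mean()) for c in confound_names}
    p = table.n_features
    coef = np.zeros((p, len(confound_names)))
    intercept = np.zeros(p)

    kinds = [d.kind for d in table.descriptors]
    for kind in set(kinds):
        cols = np.array([j for j, k in enumerate(kinds) if k == kind])
        confs = list(kind_map[kind])
        c_idx = [confound_names.index(c) for c in confs]
        x = np.column_stack([ref.metadata(c) - means[c] for c in confs])
        design = np.column_stack([np.ones(ref.n_scans), x])
        y = ref.values[:, cols]
        if np.linalg.cond(design) > _COND_THRESHOLD:
            logger.warning(
                "collinear confounds %s for kind %s; using ridge fallback", confs, kind
            )
            xtx = design.T @ design + _RIDGE * np.eye(design.shape[1])
            beta = np.linalg.solve(xtx, design.T @ y)
        else:
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        intercept[cols] = beta[0]
        coef[np.ix_(cols, c_idx)] = beta[1:].T

    return ConfoundModel(
        feature_names=table.feature_names,
        feature_kinds=kinds,
        mode=mode,
        confound_names=confound_names,
        coef=coef,
        intercept=intercept,
        confound_means=means,
        reference_group=reference_group,
    )


def apply_confound_model(model: ConfoundModel, table: FeatureTable) -> FeatureTable:
    """Subtract the predicted confound contribution from every row.

    Each value becomes ``y - sum_k beta_k (c_k - mean_k)`` with confounds
    centered at the stored training-control means; the intercept is *not*
    subtracted, so a model with all-zero slopes leaves the table unchanged.
    Applied identically to every group.
    """
    table.assert_same_features(model.feature_names)
    c = _confound_matrix(table, model.confound_names)
    c = c - np.array([model.confound_means[k] for k in model.confound_names])
    return table.with_values(table.values - c @ model.coef.T)


def deconfound_within_folds(
    table: FeatureTable,
    folds: np.ndarray,
    mode: str = "standard",
) -> FeatureTable:
    """Per-fold deconfounded table assembled across folds.

    ``folds`` assigns each row a fold label; for each fold, a confound model
    is fitted on the reference-group rows *outside* that fold and applied to
    the fold's rows.  A test row therefore never influences its own
    deconfounding fit.  With a single fold label this degenerates to
    fit-plus-apply on the full table.
    """
    folds = np.asarray(folds)
    if folds.shape != (table.n_scans,):
        raise ValueError("folds must assign one label per row")
    out = table.values.copy()
    unique = np.unique(folds)
    for f in unique:
        test_mask = folds == f
        train_idx = np.flatnonzero(~test_mask) if len(unique) > 1 else np.arange(table.n_scans)
        model = fit_confound_model(table, train_idx, mode=mode)
        adjusted = apply_confound_model(model, table.subset(test_mask))
        out[test_mask] = adjusted.values
    return table.with_values(out)
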