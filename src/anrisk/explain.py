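"""Explainable-AI analyses: activation patterns, reliability, permutation
importance, and connectome contextualization.

For a linear decoder, the interpretable importance of each input feature is
its *activation pattern*: here, the Pearson correlation of the
(deconfounded) feature with the ML-based risk score.  A positive sign means
higher values of the feature are characteristic of the patient group.
Per-feature *reliability* is the fraction of stratified subsamples of the
dataset in which that feature's importance is significant after Bonferroni
correction.  *Permutation importance* — the drop in PR-AUC when a feature's
column is shuffled across held-out rows — isolates features carrying unique
(non-redundant) classification information.

Importance profiles of cortical features are contextualized against brain
network organization by correlating them with weighted degree centrality
(the summed connection weights of each region — high values mark hubs) of a
normative connectome.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedShuffleSplit

from ._seeds import rng_for, subseed
from .data import ConnectivityMatrix, FeatureKind, FeatureTable
from .errors import AlignmentError
from .metrics import pr_auc
from .pipeline import FittedPipeline, PipelineConfig, _task_rows, fit_pipeline, risk_scores

logger = logging.getLogger(__name__)

__all__ = [
    "ImportanceProfile",
    "activation_pattern",
    "importance_reliability",
    "permutation_importance",
    "weighted_degree_centrality",
    "contextualize_importance",
    "default_region_map",
]


@dataclass
class ImportanceProfile:
    """Per-feature activation-pattern importance with significance flags."""

    feature_names: list[str]
    importance: np.ndarray  # Pearson r in [-1, 1]; NaN where undefined
    p_values: np.ndarray
    significant: np.ndarray  # after the stated correction at the stated alpha
    alpha: float
    correction: str
    reliability: np.ndarray | None = None  # in [0, 1]
    permutation_importance: np.ndarray | None = None  # metric drop
    metadata: dict = field(default_factory=dict)

    def as_rows(self) -> list[dict]:
        rows = []
        for j, name in enumerate(self.feature_names):
            rows.append(
                {
                    "feature": name,
                    "importance": float(self.importance[j]),
                    "p_value": float(self.p_values[j]),
                    "significant": bool(self.significant[j]),
                    "reliability": (
                        float(self.reliability[j]) if self.reliability is not None else None
                    ),
                    "permutation_importance": (
                        float(self.permutation_importance[j])
                        if self.permutation_importance is not None
                        else None
                    ),
                }
            )
        return rows


def _pearson_with_p(x: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-column Pearson r of ``x`` with ``v`` and two-sided p."""
    n = len(v)
    xc = x - x.mean(axis=0)
    vc = v - v.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sv = np.sqrt((vc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ vc) / (sx * sv)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    undefined = (sx == 0) | (sv == 0)
    r[undefined] = np.nan
    p[undefined] = np.nan
    return r, p


def activation_pattern(
    deconfounded: FeatureTable | np.ndarray,
    risk: np.ndarray,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    feature_names: Sequence[str] | None = None,
) -> ImportanceProfile:
    """Per-feature Pearson correlation with the risk score, with significance.

    Expects *deconfounded* features (out-of-fold risk scores from nested CV
    avoid circular training-set correlations).  Zero-variance features get
    NaN importance and are flagged non-significant rather than raising.
    """
    if isinstance(deconfounded, FeatureTable):
        x = deconfounded.values
        names = deconfounded.feature_names
    else:
        x = np.asarray(deconfounded, dtype=float)
        names = list(feature_names) if feature_names is not None else [
            f"feature_{j}" for j in range(x.shape[1])
        ]
    risk = np.asarray(risk, dtype=float).ravel()
    if x.shape[0] != len(risk):
        raise ValueError("risk must align with table rows")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 rows")

    r, p = _pearson_with_p(x, risk)
    if correction == "bonferroni":
        threshold = alpha / x.shape[1]
    elif correction == "none":
        threshold = alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    significant = np.where(np.isnan(p), False, p < threshold)
    return ImportanceProfile(
        feature_names=names,
        importance=r,
        p_values=p,
        significant=significant.astype(bool),
        alpha=alpha,
        correction=correction,
    )


def importance_reliability(
    table: FeatureTable,
    task,
    config: PipelineConfig,
    n_subsamples: int = 100,
    subsample_fraction: float = 0.9,
    alpha: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Fraction of stratified subsamples where each feature's importance is
    significant (Bonferroni over features).

    Each subsample (without replacement) refits the full pipeline and
    recomputes the activation pattern from the refit model's risk scores on
    its own deconfounded rows.
    """
    sub, y, an_group = _task_rows(table, task)
    splitter = StratifiedShuffleSplit(
        n_splits=n_subsamples,
        train_size=subsample_fraction,
        random_state=subseed(seed, "reliability"),
    )
    counts = np.zeros(table.n_features)
    for s, (idx, _) in enumerate(splitter.split(sub.values, y)):
        piece = sub.subset(idx)
        model = fit_pipeline(piece, an_group, config)
        from .deconfound import apply_confound_model

        xd = apply_confound_model(model.confound_model, piece)
        profile = activation_pattern(xd, model.training_scores, alpha=alpha)
        counts += profile.significant
    return counts / n_subsamples


def permutation_importance(
    model: FittedPipeline,
    test_table: FeatureTable,
    n_repeats: int = 25,
    seed: int = 0,
) -> np.ndarray:
    """Mean PR-AUC drop when each feature's column is shuffled across test rows.

    Test rows must belong to subjects disjoint from the model's training
    subjects.  Exploits the affine form of the risk score: permuting raw
    column *j* changes the score only through that column's contribution.
    """
    overlap = set(test_table.subject_ids) & set(model.training_subject_ids)
    if overlap:
        raise ValueError(
            f"test rows overlap the model's training subjects (e.g. {sorted(overlap)[:3]})"
        )
    sub, y, _ = _task_rows(test_table, model.positive_group)
    base_scores = risk_scores(model, sub)
    baseline = pr_auc(base_scores, y)
    w = model.feature_weights
    x = sub.values
    rng = rng_for(seed, "permutation-importance")
    drops = np.zeros(sub.n_features)
    for j in range(sub.n_features):
        contrib = x[:, j] * w[j]
        acc = 0.0
        for _ in range(n_repeats):
            perm = rng.permutation(len(y))
            acc += pr_auc(base_scores - contrib + contrib[perm], y)
        drops[j] = baseline - acc / n_repeats
    return drops


# ---------------------------------------------------------------------------
# Connectome contextualization
# ---------------------------------------------------------------------------


def weighted_degree_centrality(conn: ConnectivityMatrix) -> np.ndarray:
    """Row sums of the connectivity weights (the diagonal is zero by type)."""
    return conn.weights.sum(axis=1)


def default_region_map() -> dict[str, str]:
    """The shipped mapping from cortical feature names to connectome labels."""
    path = resources.files("anrisk").joinpath("data/dk_region_map.csv")
    with path.open() as fh:
        return {row["feature_name"]: row["connectome_label"] for row in csv.DictReader(fh)}


def contextualize_importance(
    feature_names: Sequence[str],
    importance: np.ndarray,
    conn: ConnectivityMatrix,
    region_map: Mapping[str, str] | None = None,
) -> tuple[float, float, int]:
    """Pearson correlation of a cortical importance profile with network
    centrality, aligned by region label.

    ``region_map`` maps feature names to connectome region labels; the
    shipped Desikan-Killiany mapping is used by default.  Unmatched labels
    raise :class:`~anrisk.errors.AlignmentError` listing them.  Returns
    ``(r, two-sided p, n_regions)``.
    """
    importance = np.asarray(importance, dtype=float).ravel()
    if len(importance) != len(feature_names):
        raise ValueError("importance must align with feature_names")
    if region_map is None:
        region_map = default_region_map()

    unmatched = [n for n in feature_names if n not in region_map]
    if unmatched:
        raise AlignmentError(f"features without a region mapping: {unmatched[:10]}")
    label_to_idx = {lab: i for i, lab in enumerate(conn.region_labels)}
    missing = [region_map[n] for n in feature_names if region_map[n] not in label_to_idx]
    if missing:
        raise AlignmentError(f"regions absent from the connectome: {missing[:10]}")
    if len(feature_names) < 4:
        raise ValueError("need at least 4 regions")

    centrality = weighted_degree_centrality(conn)
    aligned = np.array([centrality[label_to_idx[region_map[n]]] for n in feature_names])
    r, p = stats.pearsonr(importance, aligned)
    return float(r), float(p), len(feature_names)


def positional_region_map(table: FeatureTable, conn: ConnectivityMatrix) -> dict[str, str]:
    """Map cortical feature names to connectome labels by position.

    Valid when the connectome's region order matches the table's cortical
    descriptor order (as with generated cohorts and their connectomes).
    """
    names = [
        d.name for d in table.descriptors if d.kind == FeatureKind.CORTICAL_THICKNESS
    ]
    if len(names) != conn.n_regions:
        raise AlignmentError(
            f"{len(names)} cortical features vs {conn.n_regions} connectome regions"
        )
    return dict(zip(names, conn.region_labels))


def cortical_importance(profile: ImportanceProfile, table: FeatureTable) -> tuple[list[str], np.ndarray]:
    """Extract the cortical-thickness subvector of an importance profile."""
    idx = [
        j
        for j, d in enumerate(table.descriptors)
        if d.kind == FeatureKind.CORTICAL_THICKNESS
    ]
    names = [table.descriptors[j].name for j in idx]
    return names, profile.importance[idx]
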