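"""End-to-end study orchestration.

:func:`run_study` executes the full analysis replica from one configuration:
(optional) cohort simulation, per-task nested cross-validation, permutation
tests, confound deviance partitioning (age+eTIV, and the variant adding
BMI-SDS), explainable-AI feature importance with reliability and permutation
importance, connectome contextualization, transfer classification between
designated tasks, and the risk-score -> outcome GLM.  A single master seed
propagates deterministically to every stage through named substreams, so
re-running the same config and seed produces byte-identical reports
(timestamps excluded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seeds import subseed
from .cohort import GenerativeConfig, cohort_connectome, generate_cohort
from .data import (
    ACAN_TP1,
    ACAN_TP2,
    HC,
    RECAN,
    FeatureTable,
    read_connectivity_matrix,
    read_feature_table,
    write_connectivity_matrix,
    write_feature_table,
)
from .deconfound import CONFOUND_MAP, deconfound_within_folds
from .errors import AnriskError
from .explain import (
    activation_pattern,
    contextualize_importance,
    cortical_importance,
    importance_reliability,
    permutation_importance,
    positional_region_map,
)
from .inference import (
    deviance_partition,
    frozen_config,
    outcome_glm,
    permutation_test_auc,
)
from .pipeline import (
    PipelineConfig,
    fit_pipeline,
    nested_cv_evaluate,
    risk_scores,
    transfer_classify,
)

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_study"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class StudyConfig:
    """One configuration for the full study replica."""

    synthetic: GenerativeConfig | None = field(default_factory=GenerativeConfig)
    table_path: str | None = None  # used instead of simulation when set
    connectome_path: str | None = None
    tasks: tuple[str, ...] = (ACAN_TP1, ACAN_TP2, RECAN)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    n_permutations: int = 0
    permutation_frozen: bool = True
    deviance_permutations: int = 199
    reliability_subsamples: int = 100
    reliability_fraction: float = 0.9
    explain_task: str = ACAN_TP2
    permutation_importance_repeats: int = 25
    transfer_pairs: tuple[tuple[str, str], ...] = ((ACAN_TP2, ACAN_TP1),)
    run_outcome: bool = True
    run_explain: bool = True
    seed: int = 0
    out_dir: str = "anrisk_output"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            syn = dict(kwargs["synthetic"])
            for key in ("age_range", "delta_jitter"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            kwargs["synthetic"] = GenerativeConfig(**syn)
        if "pipeline" in kwargs:
            pipe = dict(kwargs["pipeline"])
            for key in ("pca_components_grid", "c_grid"):
                if key in pipe:
                    pipe[key] = tuple(pipe[key])
            kwargs["pipeline"] = PipelineConfig(**pipe)
        if "tasks" in kwargs:
            kwargs["tasks"] = tuple(kwargs["tasks"])
        if "transfer_pairs" in kwargs:
            kwargs["transfer_pairs"] = tuple(tuple(p) for p in kwargs["transfer_pairs"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Fingerprint of the scientific configuration (output path excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(_as_jsonable(payload), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _load_inputs(config: StudyConfig):
    if config.table_path is not None:
        table = read_feature_table(config.table_path)
        truth = None
    else:
        syn = replace(config.synthetic, seed=subseed(config.seed, "simulate"))
        table, truth = generate_cohort(syn)
    conn = None
    if config.connectome_path is not None:
        conn = read_connectivity_matrix(config.connectome_path)
    elif config.table_path is None:
        syn = replace(config.synthetic, seed=subseed(config.seed, "simulate"))
        conn, _ = cohort_connectome(syn)
    return table, truth, conn


def run_study(config: StudyConfig) -> dict:
    """Run every configured stage; write a JSON/CSV report bundle.

    Any stage failure aborts with the stage name while persisting the partial
    report written so far.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    stage = "setup"

    def persist() -> None:
        (out_dir / "report.json").write_text(
            json.dumps(_as_jsonable(report), indent=2, sort_keys=True)
        )

    try:
        logger.info("stage: load/simulate inputs")
        table, truth, conn = _load_inputs(config)
        write_feature_table(table, out_dir / "cohort.csv")
        if conn is not None:
            write_connectivity_matrix(conn, out_dir / "connectome.csv")

        # -- nested CV per task ------------------------------------------
        stage = "nested_cv"
        performances = {}
        for task in config.tasks:
            logger.info("stage: nested CV for %s vs HC", task)
            pipe = replace(config.pipeline, seed=subseed(config.seed, "cv", task))
            cv = nested_cv_evaluate(table, task, pipe)
            performances[task] = cv
            report["stages"].setdefault("nested_cv", {})[task] = cv.summary()
            pd.DataFrame(
                {
                    "scan_id": cv.scan_ids,
                    "label": cv.labels,
                    "oof_risk_score": cv.oof_mean_scores,
                }
            ).to_csv(out_dir / f"oof_scores_{task}.csv", index=False)
        persist()

        # -- permutation tests -------------------------------------------
        if config.n_permutations > 0:
            stage = "permutation_tests"
            report["stages"]["permutation_tests"] = {}
            for task in config.tasks:
                logger.info("stage: permutation test for %s vs HC", task)
                pipe = replace(config.pipeline, seed=subseed(config.seed, "cv", task))
                if config.permutation_frozen:
                    chosen = performances[task].chosen_params
                    ks = sorted(c["n_components"] for c in chosen)
                    cs = sorted(c["C"] for c in chosen)
                    pipe = frozen_config(pipe, ks[len(ks) // 2], cs[len(cs) // 2])
                res = permutation_test_auc(
                    table,
                    task,
                    pipe,
                    n_permutations=config.n_permutations,
                    seed=subseed(config.seed, "perm", task),
                    observed=performances[task],
                )
                report["stages"]["permutation_tests"][task] = {
                    m: {"observed": r.observed, "p_value": r.p_value}
                    for m, r in res.items()
                }
            persist()

        # -- confound deviance partitioning ------------------------------
        stage = "confound_assessment"
        report["stages"]["confound_assessment"] = {}
        for task in config.tasks:
            cv = performances[task]
            sub = table.subset(table.group_mask(task, HC))
            partitions = {}
            for mode, confs in (
                ("age_etiv", ("age", "etiv")),
                ("age_etiv_bmi", ("age", "etiv", "bmi_sds")),
            ):
                conf_mat = np.column_stack([sub.metadata(c) for c in confs])
                part = deviance_partition(
                    cv.oof_mean_scores,
                    conf_mat,
                    cv.labels,
                    confound_names=list(confs),
                    n_permutations=config.deviance_permutations,
                    seed=subseed(config.seed, "deviance", task, mode),
                )
                partitions[mode] = {
                    "model_exclusive": part.model_exclusive,
                    "confound_exclusive": part.confound_exclusive,
                    "shared": part.shared,
                    "p_values": part.p_values,
                }
            report["stages"]["confound_assessment"][task] = partitions
        persist()

        # -- explainability ----------------------------------------------
        if config.run_explain:
            stage = "explainability"
            task = config.explain_task
            logger.info("stage: explainability for %s vs HC", task)
            cv = performances[task]
            sub = table.subset(table.group_mask(task, HC))
            folds = np.arange(sub.n_scans) % config.pipeline.outer_folds
            deconf = deconfound_within_folds(
                sub, folds, mode=config.pipeline.deconfound_mode
            )
            profile = activation_pattern(deconf, cv.oof_mean_scores)
            profile.reliability = importance_reliability(
                table,
                task,
                replace(config.pipeline, seed=subseed(config.seed, "rel", task)),
                n_subsamples=config.reliability_subsamples,
                subsample_fraction=config.reliability_fraction,
                seed=subseed(config.seed, "reliability", task),
            )
            # permutation importance on a held-out split (disjoint subjects)
            rng = np.random.default_rng(subseed(config.seed, "permimp-split", task))
            perm_split = rng.permutation(sub.n_scans)
            n_train = int(0.7 * sub.n_scans)
            pi_model = fit_pipeline(
                sub.subset(perm_split[:n_train]),
                task,
                replace(config.pipeline, seed=subseed(config.seed, "permimp", task)),
            )
            profile.permutation_importance = permutation_importance(
                pi_model,
                sub.subset(perm_split[n_train:]),
                n_repeats=config.permutation_importance_repeats,
                seed=subseed(config.seed, "permimp-shuffle", task),
            )
            pd.DataFrame(profile.as_rows()).to_csv(
                out_dir / f"importance_{task}.csv", index=False
            )
            report["stages"]["explainability"] = {
                "task": task,
                "n_significant": int(profile.significant.sum()),
                "n_reliable": int((profile.reliability > 0.9).sum()),
            }

            # contextualization against the connectome
            if conn is not None:
                stage = "contextualization"
                names, imp = cortical_importance(profile, sub)
                rmap = positional_region_map(sub, conn)
                r, p, n_reg = contextualize_importance(names, imp, conn, rmap)
                report["stages"]["contextualization"] = {
                    "task": task,
                    "pearson_r": r,
                    "p_value": p,
                    "n_regions": n_reg,
                }
            persist()

        # -- transfer classification -------------------------------------
        # The source model is trained on the source patients plus half the
        # controls; the other half stays out so subject-level exclusion
        # leaves controls available in the target task.
        stage = "transfer"
        report["stages"]["transfer"] = {}
        for source, target in config.transfer_pairs:
            logger.info("stage: transfer %s -> %s", source, target)
            pipe = replace(config.pipeline, seed=subseed(config.seed, "transfer", source))
            rng = np.random.default_rng(subseed(config.seed, "transfer-split", source))
            hc_idx = np.flatnonzero(table.group_mask(HC))
            hc_train = rng.permutation(hc_idx)[: len(hc_idx) // 2]
            train_rows = np.concatenate(
                [hc_train, np.flatnonzero(table.group_mask(source))]
            )
            model = fit_pipeline(table.subset(train_rows), source, pipe)
            res = transfer_classify(model, table, target)
            report["stages"]["transfer"][f"{source}->{target}"] = {
                "roc_auc": res.roc_auc,
                "pr_auc": res.pr_auc,
                "n_test": res.n_test,
                "n_excluded": res.n_excluded,
            }
        persist()

        # -- outcome prediction ------------------------------------------
        outcome = table.metadata("outcome")
        has_outcome = np.isfinite(outcome)
        if config.run_outcome and has_outcome.any() and ACAN_TP2 in config.tasks:
            stage = "outcome"
            logger.info("stage: outcome GLM")
            cv = performances[ACAN_TP2]
            sub = table.subset(table.group_mask(ACAN_TP2, HC))
            sub_outcome = sub.metadata("outcome")
            mask = np.isfinite(sub_outcome)
            fits = {
                "none": outcome_glm(sub_outcome[mask], cv.oof_mean_scores[mask])
            }
            fits["bmi_sds"] = outcome_glm(
                sub_outcome[mask],
                cv.oof_mean_scores[mask],
                covariate=sub.metadata("bmi_sds")[mask],
                covariate_name="bmi_sds",
            )
            report["stages"]["outcome"] = {
                name: {
                    "slope": fit.params["risk"],
                    "slope_p": fit.slope_p,
                    "r_squared": fit.r_squared,
                    "n": fit.n,
                }
                for name, fit in fits.items()
            }
        persist()

    except AnriskError:
        persist()
        logger.error("stage %r failed; partial outputs persisted", stage)
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the stage name
        persist()
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    return report
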