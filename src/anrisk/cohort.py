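"""Synthetic cohort generator.

Generates subject-by-feature morphometry tables with the statistical
structure the downstream analysis assumes, together with the ground truth
needed for recovery tests:

* linear age effects on all features and head-size (eTIV) effects on
  volumetric features, with per-feature slopes;
* group-dependent multivariate shifts: negative for cortical thickness and
  gray-matter volumes, positive for CSF spaces, scaled per disease stage
  (acutely underweight > partially weight-restored > long-term recovered >
  healthy controls at zero);
* hub-weighted effect magnitudes for cortical features (regions with high
  network centrality carry larger alterations);
* within-subject pairing of the two acute-patient timepoints, sharing the
  same latent severity with a smaller state scale at the second timepoint
  (partial normalization);
* an optional fraction of the group effect routed through BMI-SDS, so that
  deconfounding by BMI attenuates but does not abolish the signal;
* a low-rank-plus-diagonal residual covariance inducing the multivariate,
  network-like covariation that univariate tests miss;
* a 1-year outcome score for second-timepoint subjects driven by residual
  severity (stronger planted alteration -> worse outcome).

Features are generated on a standardized latent scale (residual SD ~ 1) and
then mapped affinely to physical units per feature (mm for thickness, mm^3
for volumes), so effect sizes are expressed in residual-SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from ._seeds import rng_for, subseed
from .data import (
    ACAN_TP1,
    ACAN_TP2,
    GROUPS,
    HC,
    RECAN,
    ConnectivityMatrix,
    FeatureKind,
    FeatureTable,
    SubjectRecord,
    connectivity_from_raw,
)
from .descriptors import default_descriptors, default_region_labels
from .errors import ConfigError
from .metrics import roc_auc

__all__ = [
    "GenerativeConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_connectome",
    "oracle_bayes_auc",
    "calibrate_gamma",
]


@dataclass
class GenerativeConfig:
    """Parameters of the generative model.

    Defaults emulate the reference study regime: group sizes 289 healthy
    controls (HC), 165 acutely underweight patients at treatment start
    (acAN_TP1), 115 of the same patients after partial weight-restoration
    (acAN_TP2), and 89 long-term weight-recovered former patients (recAN);
    110 features; state scales calibrated so the population-optimal linear
    discriminant separates TP1 strongly (oracle ROC-AUC ~ 0.9), TP2 weakly
    (~ 0.65) and recAN barely (~ 0.55).
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {HC: 289, ACAN_TP1: 165, ACAN_TP2: 115, RECAN: 89}
    )
    n_cortical: int = 68
    n_subcortical_gm: int = 30
    n_csf: int = 12

    # Confound structure (latent residual-SD units).
    age_slope_scale: float = 0.04  # per year of (age - mean age)
    etiv_slope_scale: float = 0.5  # per SD of eTIV, volumetric features only
    age_range: tuple[float, float] = (12.0, 30.0)
    etiv_mean: float = 1.5e6  # mm^3
    etiv_sd: float = 1.5e5
    bmi_means: dict[str, float] = field(
        default_factory=lambda: {HC: 0.0, ACAN_TP1: -2.5, ACAN_TP2: -1.0, RECAN: -0.2}
    )
    bmi_sd: float = 0.6

    # Group effect. delta_scale is the base per-feature magnitude (residual
    # SDs); signs follow kind (negative thickness/GM, positive CSF); gamma
    # multiplies it per group with gamma[HC] = 0.
    delta_scale: float = 0.15
    delta_jitter: tuple[float, float] = (0.5, 1.5)
    hub_coupling: float = 1.0  # lambda >= 0, cortical features only
    gamma: dict[str, float] = field(
        default_factory=lambda: {HC: 0.0, ACAN_TP1: 1.20, ACAN_TP2: 0.33, RECAN: 0.12}
    )
    severity_sd: float = 0.3
    bmi_effect_fraction: float = 0.0  # fraction of the effect routed via BMI-SDS

    # Residual covariance: low-rank + diagonal.
    noise_cov_rank: int = 5
    noise_lowrank_scale: float = 0.7
    noise_sd: float = 1.0

    # Connectome used for hub weighting of cortical effects.
    connectome_hub_spread: float = 0.5
    connectome_noise_sd: float = 0.5

    # Outcome model (second acute timepoint only); higher outcome = better.
    outcome_intercept: float = 9.0
    outcome_slope: float = 1.5
    outcome_noise_sd: float = 2.0

    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ConfigError(f"unknown groups in group_sizes: {sorted(unknown)}")
        if self.group_sizes.get(ACAN_TP2, 0) > self.group_sizes.get(ACAN_TP1, 0):
            raise ConfigError(
                "acAN_TP2 must be a subset of acAN_TP1 subjects "
                f"({self.group_sizes.get(ACAN_TP2, 0)} > {self.group_sizes.get(ACAN_TP1, 0)})"
            )
        if self.gamma.get(HC, 0.0) != 0.0:
            raise ConfigError("gamma[HC] must be 0")
        if not self.noise_sd > 0:
            raise ConfigError("noise_sd must be > 0")
        if self.hub_coupling < 0:
            raise ConfigError("hub_coupling must be >= 0")

    @property
    def n_features(self) -> int:
        return self.n_cortical + self.n_subcortical_gm + self.n_csf


@dataclass
class GroundTruth:
    """Planted quantities returned alongside a generated cohort."""

    delta_vector: np.ndarray  # per-feature effect direction (residual-SD units)
    severity: dict[str, float]  # AN subject_id -> latent severity draw
    centrality_true: np.ndarray  # latent hub weight per cortical region
    pairing: dict[str, str]  # TP1 scan_id -> TP2 scan_id for shared subjects


# ---------------------------------------------------------------------------
# Connectome
# ---------------------------------------------------------------------------


def generate_connectome(
    n_regions: int, hub_spread: float, seed: int, noise_sd: float = 0.5
) -> tuple[ConnectivityMatrix, np.ndarray]:
    """Synthetic connectome with log-normal latent hub weights.

    Edge weights are ``c_i * c_j * exp(noise)`` for latent ``c = exp(hub_spread
    * z)``, symmetric with zero diagonal; the latent ``c`` is returned as
    ground truth.  With ``hub_spread = 0`` all regions are equivalent hubs.
    """
    if n_regions < 2:
        raise ConfigError(f"n_regions must be >= 2, got {n_regions}")
    rng = np.random.default_rng(seed)
    c = np.exp(hub_spread * rng.standard_normal(n_regions))
    eta = rng.standard_normal((n_regions, n_regions))
    eta = 0.5 * (eta + eta.T)
    w = np.outer(c, c) * np.exp(noise_sd * eta)
    np.fill_diagonal(w, 0.0)
    if n_regions == 68:
        labels = default_region_labels()
    else:
        labels = [f"region_{i:03d}" for i in range(n_regions)]
    return connectivity_from_raw(labels, w), c


# ---------------------------------------------------------------------------
# Model parameters shared by the generator and the oracle
# ---------------------------------------------------------------------------


def _model_params(config: GenerativeConfig) -> dict:
    """Deterministic generative parameters derived from ``config.seed``.

    Returns the per-feature effect vector ``delta`` (before the per-group
    gamma scale), the low-rank noise loadings, per-kind slope vectors and the
    latent centrality — identical for :func:`generate_cohort` and
    :func:`oracle_bayes_auc` at the same config.
    """
    config.validate()
    p = config.n_features
    n_ct, n_gm, n_csf = config.n_cortical, config.n_subcortical_gm, config.n_csf

    kinds = np.array(
        [FeatureKind.CORTICAL_THICKNESS] * n_ct
        + [FeatureKind.SUBCORTICAL_GM_VOLUME] * n_gm
        + [FeatureKind.CSF_VOLUME] * n_csf,
        dtype=object,
    )
    volumetric = kinds != FeatureKind.CORTICAL_THICKNESS

    rng = rng_for(config.seed, "model-params")
    lo, hi = config.delta_jitter
    magnitude = config.delta_scale * rng.uniform(lo, hi, size=p)
    # cortical magnitudes carry no jitter: their spread comes from the hub
    # weighting alone, making |delta| exactly monotone in centrality
    magnitude[:n_ct] = config.delta_scale
    sign = np.where(kinds == FeatureKind.CSF_VOLUME, 1.0, -1.0)

    _, centrality = generate_connectome(
        n_ct if n_ct >= 2 else 2,
        config.connectome_hub_spread,
        subseed(config.seed, "connectome"),
        noise_sd=config.connectome_noise_sd,
    )
    centrality = centrality[:n_ct]
    hub_factor = np.ones(p)
    if n_ct:
        # normalize to mean 1 so hub_coupling does not change the overall scale
        c_norm = centrality / centrality.mean()
        hub_factor[:n_ct] = 1.0 + config.hub_coupling * c_norm
        hub_factor[:n_ct] /= hub_factor[:n_ct].mean()
    delta = sign * magnitude * hub_factor

    # Confound slopes (latent units), per feature with mild heterogeneity.
    age_sign = np.where(kinds == FeatureKind.CSF_VOLUME, 1.0, -1.0)
    age_slopes = age_sign * config.age_slope_scale * rng.uniform(0.5, 1.5, size=p)
    etiv_slopes = np.where(
        volumetric, config.etiv_slope_scale * rng.uniform(0.5, 1.5, size=p), 0.0
    )

    loadings = (
        config.noise_lowrank_scale
        * rng.standard_normal((p, config.noise_cov_rank))
        / np.sqrt(config.noise_cov_rank)
    )

    # Physical-unit mapping: baselines and scales per kind.
    base = np.empty(p)
    scale = np.empty(p)
    base[:n_ct] = rng.uniform(1.8, 3.2, size=n_ct)  # mm
    scale[:n_ct] = 0.12
    base[n_ct : n_ct + n_gm] = rng.uniform(1.5e3, 2.0e4, size=n_gm)  # mm^3
    scale[n_ct : n_ct + n_gm] = 0.06 * base[n_ct : n_ct + n_gm]
    base[n_ct + n_gm :] = rng.uniform(5e2, 1.5e4, size=n_csf)
    scale[n_ct + n_gm :] = 0.15 * base[n_ct + n_gm :]

    return {
        "kinds": kinds,
        "volumetric": volumetric,
        "delta": delta,
        "age_slopes": age_slopes,
        "etiv_slopes": etiv_slopes,
        "loadings": loadings,
        "centrality": centrality,
        "base": base,
        "scale": scale,
    }


def _latent_noise(rng: np.random.Generator, n: int, params: dict, config: GenerativeConfig) -> np.ndarray:
    p = params["loadings"].shape[0]
    z = rng.standard_normal((n, params["loadings"].shape[1])) @ params["loadings"].T
    return z + config.noise_sd * rng.standard_normal((n, p))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(config: GenerativeConfig) -> tuple[FeatureTable, GroundTruth]:
    """Generate a cohort and its ground truth, reproducibly from ``config.seed``.

    The latent value of feature *j* for scan *i* in group *g* is::

        z_ij = a_j (age_i - age_mean)
             + t_j (etiv_i - etiv_mean) / etiv_sd        [volumetric only]
             + kappa_j bmi_i                              [optional coupling]
             + gamma_g (1 + s_i) d_j                      [group effect]
             + correlated noise

    where ``s_i`` is the subject's latent severity (shared between the two
    acute timepoints) and ``d_j`` the hub-weighted signed effect.  Second
    acute-timepoint rows reuse their subject's age/eTIV draws with an updated
    BMI-SDS and a smaller ``gamma``, and carry an outcome score
    ``outcome_intercept - outcome_slope * (1 + s_i) + noise``.
    """
    params = _model_params(config)
    p = config.n_features
    n_ct = config.n_cortical
    age_mid = 0.5 * (config.age_range[0] + config.age_range[1])

    # BMI-mediated routing: kappa_j chosen so the mean BMI-mediated shift in a
    # group with mean BMI-SDS b_g equals bmi_effect_fraction of the TP1-scale
    # direct effect (direct part is scaled down accordingly for AN groups).
    frac = config.bmi_effect_fraction
    bmi_ref = config.bmi_means.get(ACAN_TP1, -2.5)
    kappa = np.zeros(p)
    if frac > 0 and bmi_ref != 0:
        kappa = frac * config.gamma.get(ACAN_TP1, 1.0) * params["delta"] / bmi_ref

    records: list[SubjectRecord] = []
    rows: list[np.ndarray] = []
    severity: dict[str, float] = {}
    pairing: dict[str, str] = {}

    # Draw TP1 subjects once; TP2 reuses the first n_TP2 of them.
    rng_subj = rng_for(config.seed, "subjects")
    n_tp1 = config.group_sizes.get(ACAN_TP1, 0)
    n_tp2 = config.group_sizes.get(ACAN_TP2, 0)
    tp1_age = rng_subj.uniform(*config.age_range, size=n_tp1)
    tp1_etiv = rng_subj.normal(config.etiv_mean, config.etiv_sd, size=n_tp1)
    tp1_sev = rng_subj.normal(0.0, config.severity_sd, size=n_tp1)

    def effect(group: str, sev: np.ndarray) -> np.ndarray:
        g = config.gamma.get(group, 0.0)
        return (1.0 - (frac if g != 0 else 0.0)) * g * np.outer(1.0 + sev, params["delta"])

    scan_counter = 0
    for group in (HC, ACAN_TP1, ACAN_TP2, RECAN):
        n_g = config.group_sizes.get(group, 0)
        if n_g == 0:
            continue
        rng_g = rng_for(config.seed, "group", group)
        if group == ACAN_TP1:
            age, etiv, sev = tp1_age, tp1_etiv, tp1_sev
            subj_ids = [f"AN{i:04d}" for i in range(n_tp1)]
        elif group == ACAN_TP2:
            age, etiv, sev = tp1_age[:n_tp2], tp1_etiv[:n_tp2], tp1_sev[:n_tp2]
            subj_ids = [f"AN{i:04d}" for i in range(n_tp2)]
        else:
            age = rng_g.uniform(*config.age_range, size=n_g)
            etiv = rng_g.normal(config.etiv_mean, config.etiv_sd, size=n_g)
            sev = rng_g.normal(0.0, config.severity_sd, size=n_g)
            prefix = "HC" if group == HC else "REC"
            subj_ids = [f"{prefix}{i:04d}" for i in range(n_g)]

        bmi = config.bmi_means.get(group, 0.0) + config.bmi_sd * rng_g.standard_normal(n_g)
        z = (
            np.outer(age - age_mid, params["age_slopes"])
            + np.outer((etiv - config.etiv_mean) / config.etiv_sd, params["etiv_slopes"])
            + np.outer(bmi, kappa)
            + effect(group, sev)
            + _latent_noise(rng_for(config.seed, "noise", group), n_g, params, config)
        )
        values = params["base"] + params["scale"] * z

        outcome_noise = rng_for(config.seed, "outcome").normal(
            0.0, config.outcome_noise_sd, size=n_g
        )
        for i in range(n_g):
            scan_id = f"scan{scan_counter:04d}"
            scan_counter += 1
            outcome = None
            if group == ACAN_TP2:
                outcome = float(
                    config.outcome_intercept
                    - config.outcome_slope * (1.0 + sev[i])
                    + outcome_noise[i]
                )
            records.append(
                SubjectRecord(
                    scan_id=scan_id,
                    subject_id=subj_ids[i],
                    group=group,
                    age=float(age[i]),
                    etiv=float(etiv[i]),
                    bmi_sds=float(bmi[i]),
                    outcome=outcome,
                )
            )
            if group in (ACAN_TP1, ACAN_TP2, RECAN):
                severity[subj_ids[i]] = float(sev[i])
        rows.append(values)

    table = FeatureTable(
        records=records,
        descriptors=_descriptors_for(config),
        values=np.vstack(rows) if rows else np.empty((0, p)),
    )
    tp1_scans = {r.subject_id: r.scan_id for r in records if r.group == ACAN_TP1}
    for r in records:
        if r.group == ACAN_TP2 and r.subject_id in tp1_scans:
            pairing[tp1_scans[r.subject_id]] = r.scan_id

    truth = GroundTruth(
        delta_vector=params["delta"].copy(),
        severity=severity,
        centrality_true=params["centrality"].copy(),
        pairing=pairing,
    )
    return table, truth


def _descriptors_for(config: GenerativeConfig):
    if (config.n_cortical, config.n_subcortical_gm, config.n_csf) == (68, 30, 12):
        return default_descriptors()
    from .data import FeatureDescriptor

    out = []
    for i in range(config.n_cortical):
        out.append(
            FeatureDescriptor(
                name=f"ct_{i:03d}_thickness",
                kind=FeatureKind.CORTICAL_THICKNESS,
                hemisphere="left" if i % 2 == 0 else "right",
                region_label=f"region_{i:03d}",
            )
        )
    for i in range(config.n_subcortical_gm):
        out.append(
            FeatureDescriptor(
                name=f"gm_{i:03d}",
                kind=FeatureKind.SUBCORTICAL_GM_VOLUME,
                hemisphere="bilateral",
                region_label=f"gm_{i:03d}",
            )
        )
    for i in range(config.n_csf):
        out.append(
            FeatureDescriptor(
                name=f"csf_{i:03d}",
                kind=FeatureKind.CSF_VOLUME,
                hemisphere="bilateral",
                region_label=f"csf_{i:03d}",
            )
        )
    return out


def cohort_connectome(config: GenerativeConfig) -> tuple[ConnectivityMatrix, np.ndarray]:
    """The connectome whose centrality weighted this cohort's cortical effects."""
    return generate_connectome(
        config.n_cortical,
        config.connectome_hub_spread,
        subseed(config.seed, "connectome"),
        noise_sd=config.connectome_noise_sd,
    )


# ---------------------------------------------------------------------------
# Oracle performance from the generative model
# ---------------------------------------------------------------------------


def oracle_bayes_auc(
    config: GenerativeConfig,
    group: str,
    n_mc: int = 20000,
    seed: int = 12345,
) -> float:
    """Monte-Carlo ROC-AUC of the population-optimal *linear* discriminant.

    Draws ``n_mc`` latent feature vectors per class from the generative model
    (confound terms omitted — they are removable in principle), fits the
    linear discriminant analytically from a large training draw (pooled
    covariance), and evaluates ROC-AUC on an independent draw.  This is the
    ceiling a linear pipeline can approach on this cohort family.
    """
    params = _model_params(config)
    g = config.gamma.get(group, 0.0)
    rng = np.random.default_rng(seed)

    def draw(n: int, with_effect: bool) -> np.ndarray:
        x = _latent_noise(rng, n, params, config)
        if with_effect:
            sev = rng.normal(0.0, config.severity_sd, size=n)
            x = x + g * (1.0 + sev)[:, None] * params["delta"]
        return x

    x0, x1 = draw(n_mc, False), draw(n_mc, True)
    mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
    xc = np.vstack([x0 - mu0, x1 - mu1])
    cov = (xc.T @ xc) / (len(xc) - 2)
    w = np.linalg.solve(cov, mu1 - mu0)

    t0, t1 = draw(n_mc, False), draw(n_mc, True)
    scores = np.concatenate([t0 @ w, t1 @ w])
    labels = np.concatenate([np.zeros(n_mc, dtype=int), np.ones(n_mc, dtype=int)])
    return roc_auc(scores, labels)


def calibrate_gamma(
    config: GenerativeConfig,
    group: str,
    target_auc: float,
    n_mc: int = 20000,
    seed: int = 12345,
    tol: float = 0.005,
    max_iter: int = 30,
) -> GenerativeConfig:
    """Return a config whose ``gamma[group]`` yields the target oracle AUC.

    Bisection on the state scale against :func:`oracle_bayes_auc`; the oracle
    AUC is strictly increasing in gamma, so this converges.
    """
    if not 0.5 < target_auc < 1.0:
        raise ConfigError("target_auc must be in (0.5, 1)")
    lo, hi = 0.0, 0.05
    cfg = replace(config, gamma=dict(config.gamma))

    def auc_at(g: float) -> float:
        cfg.gamma[group] = g
        return oracle_bayes_auc(cfg, group, n_mc=n_mc, seed=seed)

    while auc_at(hi) < target_auc:
        hi *= 2.0
        if hi > 100:
            raise ConfigError("cannot reach target AUC; increase delta_scale")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        a = auc_at(mid)
        if abs(a - target_auc) < tol:
            break
        if a < target_auc:
            lo = mid
        else:
            hi = mid
    else:
        mid = 0.5 * (lo + hi)
    cfg.gamma[group] = mid
    return cfg
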