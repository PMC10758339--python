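"""Activation patterns, reliability, permutation importance, centrality."""

import numpy as np
import pytest
from dataclasses import replace

from anrisk.cohort import GenerativeConfig, cohort_connectome, generate_cohort
from anrisk.data import ACAN_TP1, ACAN_TP2, HC, RECAN, ConnectivityMatrix
from anrisk.errors import AlignmentError
from anrisk.explain import (
    activation_pattern,
    contextualize_importance,
    cortical_importance,
    importance_reliability,
    permutation_importance,
    positional_region_map,
    weighted_degree_centrality,
)
from anrisk.pipeline import PipelineConfig, fit_pipeline

from conftest import build_table

FAST = PipelineConfig(
    pca_components_grid=(6,),
    pca_include_full=False,
    c_grid=(1.0,),
    inner_folds=3,
    inner_repeats=1,
    outer_folds=3,
    outer_repeats=1,
    seed=0,
)


class TestActivationPattern:
    def test_feature_identical_to_risk_has_importance_one(self, rng):
        risk = rng.standard_normal(50)
        x = np.column_stack([risk, rng.standard_normal(50)])
        profile = activation_pattern(x, risk)
        assert profile.importance[0] == pytest.approx(1.0)
        assert profile.significant[0]

    def test_noise_feature_is_weak_and_nonsignificant(self, rng):
        n = 500
        risk = rng.standard_normal(n)
        x = rng.standard_normal((n, 3))
        profile = activation_pattern(x, risk)
        assert np.all(np.abs(profile.importance) < 0.15)
        assert not profile.significant.any()

    def test_zero_variance_feature_flagged_not_crashed(self, rng):
        risk = rng.standard_normal(30)
        x = np.column_stack([np.full(30, 2.5), risk])
        profile = activation_pattern(x, risk)
        assert np.isnan(profile.importance[0])
        assert not profile.significant[0]
        assert profile.significant[1]

    def test_haufe_equivalence_on_standardized_features(self, rng):
        """Importance times positive per-feature scales equals the covariance
        pattern of the features with the risk score."""
        n, p = 200, 6
        x = rng.standard_normal((n, p)) @ rng.standard_normal((p, p))
        risk = x @ rng.standard_normal(p) + rng.standard_normal(n)
        profile = activation_pattern(x, risk)
        cov_pattern = [np.cov(x[:, j], risk, ddof=1)[0, 1] for j in range(p)]
        scale = x.std(axis=0, ddof=1) * risk.std(ddof=1)
        np.testing.assert_allclose(profile.importance * scale, cov_pattern, atol=1e-10)

    def test_bonferroni_is_stricter_than_uncorrected(self, rng):
        n, p = 120, 40
        risk = rng.standard_normal(n)
        x = rng.standard_normal((n, p)) + 0.18 * risk[:, None]
        bonf = activation_pattern(x, risk, correction="bonferroni")
        raw = activation_pattern(x, risk, correction="none")
        assert bonf.significant.sum() <= raw.significant.sum()


class TestReliability:
    def _cohort(self, gamma=2.5, seed=0):
        cfg = GenerativeConfig(
            group_sizes={HC: 80, ACAN_TP1: 80, ACAN_TP2: 0, RECAN: 0},
            n_cortical=10,
            n_subcortical_gm=6,
            n_csf=4,
            gamma={HC: 0.0, ACAN_TP1: gamma, ACAN_TP2: 0.0, RECAN: 0.0},
            seed=seed,
        )
        return generate_cohort(cfg)

    def test_single_subsample_reliability_is_binary(self):
        table, _ = self._cohort()
        rel = importance_reliability(table, ACAN_TP1, FAST, n_subsamples=1, seed=0)
        assert set(np.unique(rel)) <= {0.0, 1.0}

    def test_strong_signal_reliable_noise_not(self):
        """Planted features reach the high-reliability band; a pure-noise
        feature stays near zero."""
        table, truth = self._cohort(gamma=3.0)
        noisy = table.copy()
        noisy.values[:, 5] = np.random.default_rng(1).standard_normal(table.n_scans)
        rel = importance_reliability(noisy, ACAN_TP1, FAST, n_subsamples=20, seed=1)
        strongest = int(np.argmax(np.abs(truth.delta_vector)))
        assert rel[strongest] >= 0.9
        assert rel[5] <= 0.1

    def test_reliability_monotone_in_effect_size(self):
        means = []
        for gamma in (0.0, 1.2, 3.0):
            table, _ = self._cohort(gamma=gamma, seed=3)
            rel = importance_reliability(table, ACAN_TP1, FAST, n_subsamples=10, seed=3)
            means.append(rel.mean())
        assert means[0] <= means[1] + 0.05 <= means[2] + 0.10
        assert means[2] > means[0]


class TestPermutationImportance:
    def _split_model(self, seed=0, gamma=2.0):
        cfg = GenerativeConfig(
            group_sizes={HC: 120, ACAN_TP1: 120, ACAN_TP2: 0, RECAN: 0},
            n_cortical=8,
            n_subcortical_gm=4,
            n_csf=2,
            gamma={HC: 0.0, ACAN_TP1: gamma, ACAN_TP2: 0.0, RECAN: 0.0},
            seed=seed,
        )
        table, truth = generate_cohort(cfg)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(table.n_scans)
        train, test = perm[:160], perm[160:]
        train_table = table.subset(train)
        model = fit_pipeline(train_table, ACAN_TP1, FAST)
        return model, table.subset(test), train_table

    def test_training_overlap_rejected(self):
        model, _, train_table = self._split_model()
        with pytest.raises(ValueError, match="overlap"):
            permutation_importance(model, train_table, seed=0)

    def test_irrelevant_feature_has_near_zero_drop(self, rng):
        """A feature the classifier ignores cannot change the metric."""
        model, test, _ = self._split_model()
        j = 3
        model.pca_components[:, j] = 0.0  # force zero weight on feature j
        drops = permutation_importance(model, test, n_repeats=10, seed=2)
        assert abs(drops[j]) < 1e-12

    def test_single_informative_feature_has_maximal_drop(self, rng):
        n = 240
        x = rng.standard_normal((n, 6))
        groups = [HC] * (n // 2) + [ACAN_TP1] * (n // 2)
        x[n // 2 :, 0] += 2.0
        table = build_table(x, groups, ages=rng.uniform(12, 30, n))
        idx = rng.permutation(n)
        model = fit_pipeline(table.subset(idx[:160]), ACAN_TP1, FAST)
        drops = permutation_importance(model, table.subset(idx[160:]), n_repeats=20, seed=3)
        assert int(np.argmax(drops)) == 0

    def test_repeat_count_stability(self):
        model, test, _ = self._split_model(seed=5)
        d50 = permutation_importance(model, test, n_repeats=50, seed=7)
        d51 = permutation_importance(model, test, n_repeats=51, seed=8)
        assert np.max(np.abs(d50 - d51)) < 0.06


class TestCentrality:
    def test_uniform_matrix_closed_form(self):
        n, w = 6, 0.7
        weights = np.full((n, n), w)
        np.fill_diagonal(weights, 0.0)
        conn = ConnectivityMatrix(region_labels=[f"r{i}" for i in range(n)], weights=weights)
        np.testing.assert_allclose(weighted_degree_centrality(conn), (n - 1) * w)

    def test_hand_computed_three_regions(self):
        weights = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        conn = ConnectivityMatrix(region_labels=["a", "b", "c"], weights=weights)
        np.testing.assert_array_equal(weighted_degree_centrality(conn), [3.0, 4.0, 5.0])

    def test_permutation_equivariance(self, rng):
        w = np.abs(rng.standard_normal((7, 7)))
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        labels = [f"r{i}" for i in range(7)]
        conn = ConnectivityMatrix(region_labels=labels, weights=w)
        perm = rng.permutation(7)
        conn_p = ConnectivityMatrix(
            region_labels=[labels[i] for i in perm], weights=w[np.ix_(perm, perm)]
        )
        np.testing.assert_allclose(
            weighted_degree_centrality(conn_p), weighted_degree_centrality(conn)[perm]
        )


class TestContextualize:
    def test_exact_anticorrelation(self, rng):
        w = np.abs(rng.standard_normal((8, 8)))
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        labels = [f"r{i}" for i in range(8)]
        conn = ConnectivityMatrix(region_labels=labels, weights=w)
        centrality = weighted_degree_centrality(conn)
        names = [f"f{i}" for i in range(8)]
        mapping = dict(zip(names, labels))
        r, p, n = contextualize_importance(names, -centrality, conn, mapping)
        assert r == pytest.approx(-1.0)
        assert n == 8

    def test_unmatched_labels_listed(self, rng):
        w = np.zeros((4, 4))
        conn = ConnectivityMatrix(region_labels=["a", "b", "c", "d"], weights=w)
        with pytest.raises(AlignmentError, match="mystery"):
            contextualize_importance(
                ["mystery"], np.array([0.1]), conn, {"other": "a"}
            )

    def test_default_map_covers_all_cortical_features(self):
        from anrisk.descriptors import default_descriptors
        from anrisk.explain import default_region_map

        mapping = default_region_map()
        cortical = [
            d.name for d in default_descriptors() if d.name.endswith("_thickness")
        ]
        assert set(cortical) <= set(mapping)

    def test_positional_map_on_generated_cohort(self):
        cfg = GenerativeConfig(
            group_sizes={HC: 10, ACAN_TP1: 10, ACAN_TP2: 0, RECAN: 0}, seed=0
        )
        table, _ = generate_cohort(cfg)
        conn, _ = cohort_connectome(cfg)
        mapping = positional_region_map(table, conn)
        assert len(mapping) == 68
        # names and labels describe the same region, e.g. lh_bankssts
        assert mapping["lh_bankssts_thickness"] == "lh_bankssts"
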