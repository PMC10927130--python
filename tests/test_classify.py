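"""Tests for feature selection and Mahalanobis LOO-kNN classification."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rptfusion.classify import (
    COMBINATIONS,
    KNNConfig,
    knn_loo,
    kruskal_dunn,
    mahalanobis_transform,
    run_combinations,
    select_features,
)


class TestKruskalDunn:
    def test_toy_mean_rank_formula(self):
        values = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        labels = np.array(["a", "a", "b", "b", "c", "c"])
        row = kruskal_dunn(values, labels)
        # pooled ranks 1..6; mean ranks 1.5 / 3.5 / 5.5; no ties
        se = np.sqrt((6 * 7 / 12) * (1 / 2 + 1 / 2))
        z_ab = (1.5 - 3.5) / se
        assert row.pairwise_p[("a", "b")] == pytest.approx(
            2 * (1 - 0.5 * (1 + math.erf(abs(z_ab) / np.sqrt(2)))), abs=1e-9
        )
        assert row.pairwise_p[("a", "c")] < row.pairwise_p[("a", "b")]

    def test_constant_feature_not_selected(self):
        row = kruskal_dunn(np.ones(30), np.repeat(["a", "b", "c"], 10))
        assert not row.selected and np.isnan(row.kw_p)

    def test_null_calibration(self):
        """Selection rate of identical-distribution groups stays near the
        nominal level."""
        rng = np.random.default_rng(0)
        labels = np.repeat(["a", "b", "c"], 25)
        hits = sum(
            kruskal_dunn(rng.standard_normal(75), labels).selected
            for _ in range(1000)
        )
        assert 0.02 <= hits / 1000 <= 0.09

    def test_shifted_group_power(self):
        """A 2-pooled-sd shift in one group of 25 is detected essentially
        always."""
        rng = np.random.default_rng(1)
        labels = np.repeat(["a", "b", "c"], 25)
        hits = 0
        for _ in range(100):
            v = rng.standard_normal(75)
            v[50:] += 2.0
            hits += kruskal_dunn(v, labels).selected
        assert hits >= 95

    def test_select_features_table(self, small_cohort):
        _, cohort = small_cohort
        valid = cohort[cohort["valid"]]
        tab = select_features(valid, ["mean_k_inc", "mean_k_dec"])
        assert set(tab["feature"]) == {"mean_k_inc", "mean_k_dec"}
        assert "q_CD_vs_CTRL" in tab.columns


class TestMahalanobisTransform:
    def test_identity_covariance_unchanged(self):
        # two groups, each with exactly identity sample covariance
        base = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]]) * np.sqrt(3 / 2)
        X = np.vstack([base, base + 5])
        labels = np.array(["a"] * 4 + ["b"] * 4)
        W = mahalanobis_transform(X, labels)
        assert np.allclose(W, np.eye(2), atol=1e-10)

    def test_diagonal_scaling(self):
        # pooled covariance diag(4, 1) -> scaling (1/2, 1)
        a, b = np.sqrt(3) * 2, np.sqrt(3) / 2 * 2
        base = np.array([[a, 0], [-a, 0], [0, b], [0, -b]]) / np.sqrt(2)
        X = np.vstack([base, base])
        labels = np.array(["a"] * 4 + ["b"] * 4)
        S = np.cov(base.T) * 1.0
        W = mahalanobis_transform(X, labels)
        assert np.allclose(W @ S @ W, np.eye(2), atol=1e-10)
        assert np.allclose(np.diag(W), [1 / np.sqrt(S[0, 0]), 1 / np.sqrt(S[1, 1])])

    def test_whitening_property_random(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((80, 5)) @ rng.uniform(0.5, 2, (5, 5))
        labels = np.repeat(["a", "b"], 40)
        W = mahalanobis_transform(X, labels)
        Xt = X @ W
        S = np.zeros((5, 5))
        dof = 0
        for g in ("a", "b"):
            xc = Xt[labels == g] - Xt[labels == g].mean(axis=0)
            S += xc.T @ xc
            dof += (labels == g).sum() - 1
        assert np.allclose(S / dof, np.eye(5), atol=1e-8)

    def test_singular_without_ridge_raises(self):
        X = np.ones((10, 2))
        X[:, 1] = np.arange(10)
        X = np.column_stack([X[:, 1], X[:, 1]])  # rank 1
        labels = np.repeat(["a", "b"], 5)
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            mahalanobis_transform(X, labels, ridge=0)
        W = mahalanobis_transform(X, labels, ridge=1e-6)  # ridge fallback works
        assert np.all(np.isfinite(W))


def _brute_force_knn(X, labels, k):
    """Independent plain-Euclidean LOO-kNN with training-share priors."""
    n = len(labels)
    preds = []
    classes = sorted(set(labels))
    for i in range(n):
        train = [j for j in range(n) if j != i]
        d = [(np.sqrt(((X[j] - X[i]) ** 2).sum()), j) for j in train]
        d.sort()
        votes = [labels[j] for _, j in d[:k]]
        priors = {g: sum(labels[j] == g for j in train) / len(train)
                  for g in classes}
        scores = {g: priors[g] * votes.count(g) / k for g in classes}
        best = max(scores.values())
        tied = sorted([g for g in classes if scores[g] == best],
                      key=lambda g: (-priors[g], g))
        preds.append(tied[0])
    return np.array(preds)


class TestKNN:
    def test_duplicated_points_self_evident(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((8, 2))
        X = np.repeat(pts, 5, axis=0)
        labels = np.repeat(rng.choice(["a", "b"], 8), 5)
        if min((labels == "a").sum(), (labels == "b").sum()) < 6:
            labels = np.repeat(["a", "b", "a", "b", "a", "b", "a", "b"], 5)
        rep = knn_loo(X, labels, KNNConfig(transform="none"))
        assert (rep["pct_correct"] == 100.0).all()

    def test_separated_clusters(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.standard_normal((20, 3)),
                       rng.standard_normal((20, 3)) + 10.0])
        labels = np.repeat(["a", "b"], 20)
        rep = knn_loo(X, labels, KNNConfig())
        assert (rep["n_correct"].sum() / rep["n"].sum()) >= 0.95

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 1, (8, 2))
        labels = np.array(["a", "b", "a", "b", "b", "a", "b", "a"])
        rep = knn_loo(X, labels, KNNConfig(k=1, transform="none"))
        preds = _brute_force_knn(X, labels, 1)
        for g in ("a", "b"):
            expected = int(((preds == labels) & (labels == g)).sum())
            got = int(rep.loc[rep["class"] == g, "n_correct"].iloc[0])
            assert got == expected

    def test_label_permutation_accuracy_near_prior(self):
        """Shuffled labels on separable data give accuracy near the larger
        prior (no information leaks through the LOO folds)."""
        rng = np.random.default_rng(4)
        X = np.vstack([rng.standard_normal((30, 2)),
                       rng.standard_normal((20, 2)) + 8.0])
        labels = np.array(["a"] * 30 + ["b"] * 20)
        accs = []
        for _ in range(20):
            perm = rng.permutation(50)
            rep = knn_loo(X, labels[perm], KNNConfig())
            accs.append(rep["n_correct"].sum() / 50)
        # uninformative labels: accuracy stays near chance/prior level,
        # bounded above by the majority prior (plus noise) and far from the
        # ~100% the separated clusters would give if information leaked
        mean_acc = np.mean(accs)
        assert mean_acc <= 0.6 + 0.1
        assert 0.3 <= mean_acc <= 0.75

    def test_class_too_small_rejected(self):
        X = np.random.default_rng(0).standard_normal((8, 2))
        labels = np.array(["a"] * 5 + ["b"] * 3)
        with pytest.raises(ValueError, match="k\\+1"):
            knn_loo(X, labels, KNNConfig(k=5))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            KNNConfig(k=0).validate()
        with pytest.raises(ValueError):
            KNNConfig(priors={"a": 0.6, "b": 0.6}).validate()


class TestRunCombinations:
    def test_report_shape_and_conservation(self, coupled_cohort):
        _, cohort = coupled_cohort
        report = run_combinations(
            cohort, ["radial_dispersion"], ["Right Thalamus", "Left Thalamus"]
        )
        entries = report[["pair", "combination"]].drop_duplicates()
        assert len(entries) == 18          # 3 pairs x 6 combinations
        assert set(report["combination"]) == set(COMBINATIONS)
        ran = report[~report["not_run"].astype(bool)]
        assert (ran["n_correct"] + ran["n_misclassified"] == ran["n"]).all()
        pcts = 100.0 * ran["n_correct"] / ran["n"]
        assert np.allclose(ran["pct_correct"], pcts)

    def test_prior_proportions_at_study_sizes(self):
        """Class priors default to training proportions; at 40 vs 25 the
        full-sample proportions are 61.5% / 38.5%."""
        rng = np.random.default_rng(5)
        X = np.vstack([rng.standard_normal((40, 2)),
                       rng.standard_normal((25, 2)) + 6.0])
        labels = np.array(["CTRL"] * 40 + ["MDD"] * 25)
        assert round(40 / 65, 3) == 0.615 and round(25 / 65, 3) == 0.385
        cfg = KNNConfig(priors={"CTRL": 40 / 65, "MDD": 25 / 65})
        cfg.validate()
        rep = knn_loo(X, labels, cfg)
        assert rep["n"].sum() == 65
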