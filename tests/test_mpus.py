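"""ICC, SVM-RFE, SMOTE, score map, metrics, and nested-CV behavior."""

import numpy as np
import pandas as pd
import pytest

from usradiomics.mpus import (
    CVResult,
    SelectionConfig,
    auc_rank,
    balanced_accuracy_threshold,
    classification_metrics,
    feature_frequency,
    group_stats,
    icc_2_1,
    icc_filter,
    nested_cv,
    rfe_rank,
    smote,
    train_scoremap,
)
from usradiomics.synth import simulate_feature_cohort

FAST = SelectionConfig(
    inner_folds=(3,),
    inner_iterations=1,
    bootstrap_scoremaps=2,
    outer_partitions=5,
    outer_iterations=1,
    box_constraints=(0.01, 1.0),
    kernel_scales=(1.0, 3.0),
    max_features=4,
    seed=0,
)


class TestICC:
    def test_hand_worked_table_matches_closed_form(self):
        """Three raters, six subjects: value checked against the published
        two-way absolute-agreement single-measure formula via pingouin."""
        data = np.array(
            [[9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2], [10, 5, 6], [6, 2, 4]],
            dtype=float,
        )
        got = icc_2_1(data)
        pingouin = pytest.importorskip("pingouin")
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(6), 3),
                "rater": np.tile(np.arange(3), 6),
                "score": data.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        )
        sel = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = ref.loc[sel, "ICC"].iloc[0]
        assert got == pytest.approx(icc2, abs=1e-10)

    def test_perfect_agreement_is_one(self):
        col = np.array([[1.0], [2.0], [5.0], [9.0]])
        data = np.repeat(col, 3, axis=1)
        assert icc_2_1(data) == pytest.approx(1.0)

    def test_pure_noise_near_zero(self, rng):
        data = rng.normal(size=(40, 4))
        assert abs(icc_2_1(data)) < 0.3

    def test_filter_retains_stable_drops_noisy(self, rng):
        n_pat, n_rep = 12, 3
        idx = pd.MultiIndex.from_product(
            [range(n_pat), range(n_rep)], names=["patient", "replicate"]
        )
        stable_vals = np.repeat(rng.normal(size=n_pat), n_rep)
        stable = stable_vals + rng.normal(0, 0.01, n_pat * n_rep)
        noisy = rng.normal(size=n_pat * n_rep)
        reps = pd.DataFrame({"stable": stable, "noisy": noisy}, index=idx)
        kept = icc_filter(reps, 0.90)
        assert kept == ["stable"]


class TestRFE:
    def test_informative_feature_ranked_first(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 60
            y = np.repeat([0, 1], n // 2)
            X = r.normal(size=(n, 8))
            X[:, 3] += 3.0 * y  # the only informative feature
            if rfe_rank(X, y)[0] == 3:
                hits += 1
        assert hits >= 9

    def test_duplicated_feature_redundancy(self, rng):
        """A duplicated signal splits its SVM weight, so one copy is
        eliminated before an equally strong independent feature."""
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 5))
        X[:, 0] += 2.0 * y
        X[:, 1] = X[:, 0]  # exact duplicate
        X[:, 2] = rng.normal(size=n) + 2.0 * y  # independent, same strength
        rank = rfe_rank(X, y)
        worse_dup = max(rank.index(0), rank.index(1))
        assert rank.index(2) < worse_dup
        # noise features rank below every informative one
        best_noise = min(rank.index(3), rank.index(4))
        assert best_noise > min(rank.index(0), rank.index(1))
        assert best_noise > rank.index(2)

    def test_single_feature_is_rank_one(self):
        y = np.array([0, 0, 1, 1])
        X = np.array([[0.0], [0.1], [1.0], [1.1]])
        assert rfe_rank(X, y) == [0]

    def test_constant_feature_eliminated_first(self, rng):
        n = 40
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 4))
        X[:, 2] = 5.0  # constant
        rank = rfe_rank(X, y)
        assert rank[-1] == 2


class TestSMOTE:
    def test_balances_five_vs_ten(self, rng):
        X = np.vstack([rng.normal(0, 1, (5, 3)), rng.normal(5, 1, (10, 3))])
        y = np.array([1] * 5 + [0] * 10)
        Xb, yb = smote(X, y, k=5, rng=rng)
        assert (yb == 1).sum() == 10
        assert (yb == 0).sum() == 10

    def test_synthetic_points_interpolate_minority(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (4, 2)), rng.normal(10, 0.1, (8, 2))])
        y = np.array([1] * 4 + [0] * 8)
        Xb, yb = smote(X, y, rng=rng)
        new = Xb[len(X):]
        # every synthetic sample lies in the minority cluster's hull vicinity
        assert np.all(np.abs(new) < 1.0)

    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.repeat([0, 1], 5)
        Xb, yb = smote(X, y, rng=rng)
        assert Xb.shape == X.shape


class TestScoreMap:
    def test_separable_clusters_trained_perfectly(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (10, 5)), rng.normal(3, 0.3, (10, 5))])
        y = np.repeat([0, 1], 10)
        sm = train_scoremap(X, y, rng=rng)
        s = sm.score(X)
        assert auc_rank(s, y) == 1.0
        assert np.all(s[y == 1] > 0)
        assert sm.components.shape[0] == 3

    def test_small_class_rejected(self, rng):
        X = rng.normal(size=(8, 3))
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="at least 3"):
            train_scoremap(X, y, rng=rng)

    def test_threshold_never_hurts_balanced_accuracy(self, rng):
        scores = rng.normal(size=50)
        y = (rng.uniform(size=50) > 0.6).astype(int)
        t = balanced_accuracy_threshold(scores, y)

        def ba(thr):
            pred = scores > thr
            return 0.5 * (
                (pred & (y == 1)).sum() / (y == 1).sum()
                + (~pred & (y == 0)).sum() / (y == 0).sum()
            )

        assert ba(t) >= ba(0.0)


class TestMetrics:
    def test_perfect_separation(self):
        s = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([0, 0, 1, 1])
        m = classification_metrics(s, y, n_boot=100)
        assert m["auc"]["value"] == 1.0
        assert m["sensitivity"]["value"] == 1.0
        assert m["specificity"]["value"] == 1.0

    def test_auc_matches_exhaustive_pair_counting(self):
        """4-patient oracle: count concordant/tied pairs by hand."""
        s = np.array([0.3, 0.1, 0.3, -0.2])
        y = np.array([1, 0, 0, 1])
        pairs = [(i, j) for i in range(4) for j in range(4) if y[i] == 1 and y[j] == 0]
        brute = np.mean([1.0 if s[i] > s[j] else 0.5 if s[i] == s[j] else 0.0
                         for i, j in pairs])
        assert auc_rank(s, y) == pytest.approx(brute)

    def test_shuffled_labels_near_half(self, rng):
        s = rng.normal(size=2000)
        y = rng.integers(0, 2, 2000)
        assert abs(auc_rank(s, y) - 0.5) < 0.05

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc_rank(np.array([1.0, 2.0]), np.array([1, 1]))


class TestGroupStats:
    def test_identical_groups(self):
        s = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        out = group_stats(s, y)
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_textbook_two_sample(self):
        """t and p match the closed form computed independently."""
        g1 = np.array([5.0, 6.0, 7.0, 8.0])
        g0 = np.array([1.0, 2.0, 3.0, 4.0])
        out = group_stats(np.concatenate([g1, g0]),
                          np.array([1] * 4 + [0] * 4))
        n = 4
        sp2 = (g1.var(ddof=1) + g0.var(ddof=1)) / 2
        t_manual = (g1.mean() - g0.mean()) / np.sqrt(sp2 * 2 / n)
        assert out["t"] == pytest.approx(t_manual)

    def test_monotone_spearman(self):
        from usradiomics.mpus import spearman

        rho, _ = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == 1.0


class TestNestedCV:
    @staticmethod
    def _cohort(effect, seed=0):
        table, reps = simulate_feature_cohort(
            n_per_group=10, effect_sd=effect, seed=seed
        )
        pre = table.xs("pre", level="timepoint")
        y = pre["label"].astype(int)
        X = pre.drop(columns="label")
        return X, y, reps

    def test_determinism(self):
        X, y, _ = self._cohort(1.0)
        r1 = nested_cv(X, y, FAST)
        r2 = nested_cv(X, y, FAST)
        pd.testing.assert_series_equal(r1.scores, r2.scores)
        assert r1.metrics == r2.metrics

    def test_strong_effect_high_auc(self):
        X, y, _ = self._cohort(3.0, seed=1)
        res = nested_cv(X, y, FAST)
        assert res.metrics["auc"]["value"] >= 0.9

    def test_label_permutation_canary(self):
        """Leakage canary: with permuted labels the aggregated AUC must sit
        in the chance band."""
        X, y, _ = self._cohort(3.0, seed=2)
        rng = np.random.default_rng(7)
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        res = nested_cv(X, y_perm, FAST)
        assert 0.2 <= res.metrics["auc"]["value"] <= 0.8

    def test_aggregated_score_matches_fold_log(self):
        """Recompute per-patient aggregates from the persisted fold log."""
        X, y, _ = self._cohort(2.0, seed=3)
        cfg = SelectionConfig(**{**FAST.__dict__, "outer_iterations": 2})
        res = nested_cv(X, y, cfg)
        sums = {}
        counts = {}
        for _, row in res.fold_log.iterrows():
            pats = row["test_patients"].split(";")
            svals = [float(v) for v in row["test_scores"].split(";")]
            for p, s in zip(pats, svals):
                sums[p] = sums.get(p, 0.0) + s
                counts[p] = counts.get(p, 0) + 1
        for p in X.index:
            assert res.scores[p] == pytest.approx(sums[p] / counts[p])

    def test_icc_stage_drops_unstable_columns(self):
        X, y, reps = self._cohort(2.0, seed=4)
        res = nested_cv(X, y, FAST, replicates=reps)
        # the last 20 columns are re-drawn per replicate (unstable, ICC ~ 0)
        unstable = set(X.columns[-20:])
        selected = set(res.selection_counts[res.selection_counts > 0].index)
        assert not (selected & unstable)

    def test_feature_frequency_report(self):
        X, y, _ = self._cohort(3.0, seed=5)
        res = nested_cv(X, y, FAST)
        freq = feature_frequency(res, top=5)
        assert list(freq.columns) == ["feature", "count", "region", "domain"]
        assert (freq["count"] > 0).any()
        assert set(freq["region"]) <= {"tumor", "peri_tumor"}
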