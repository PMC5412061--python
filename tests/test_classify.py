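import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compseq import classify
from compseq.classify import (auc_mann_whitney, cat_ranking, cat_scores,
                              compare_models, confusion_metrics, cv_auc,
                              evaluate, fit_lda, roc_points,
                              select_and_train, shrinkage_correlation,
                              stratified_folds, t_scores)
from compseq.impute import ImputedStack, ImputationConfig, mice_pmm


def labels(n1, n0):
    return np.array(["CA"] * n1 + ["NC"] * n0)


def oracle_auc(scores, y):
    """Enumerate all case-control pairs."""
    pos = [s for s, c in zip(scores, y) if c == "CA"]
    neg = [s for s, c in zip(scores, y) if c == "NC"]
    wins = sum((p > q) + 0.5 * (p == q)
               for p, q in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def oracle_shrinkage(X):
    """Literal re-computation of the shrinkage estimator with loops."""
    n, p = X.shape
    sd = X.std(axis=0, ddof=1)
    Xs = np.zeros_like(X, dtype=float)
    for j in range(p):
        if sd[j] > 0:
            Xs[:, j] = (X[:, j] - X[:, j].mean()) / sd[j]
    R = np.eye(p)
    var_sum, sq_sum = 0.0, 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            w = Xs[:, i] * Xs[:, j]
            r = w.sum() / (n - 1)
            R[i, j] = r
            var_sum += n / (n - 1) ** 3 * ((w - w.mean()) ** 2).sum()
            sq_sum += r ** 2
    lam = 1.0 if sq_sum == 0 else min(1.0, max(0.0, var_sum / sq_sum))
    Rs = (1 - lam) * R
    np.fill_diagonal(Rs, 1.0)
    return Rs, lam


def oracle_inv_sqrt(R, eps=1e-8):
    """Matrix inverse square root recomputed via numpy.linalg.eig."""
    vals, vecs = np.linalg.eig(R)
    vals = np.maximum(vals.real, eps)
    vecs = vecs.real
    return vecs @ np.diag(vals ** -0.5) @ np.linalg.inv(vecs)


class TestTScores:
    def test_null_features_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 5))
        t = t_scores(X, labels(200, 200))
        assert np.all(np.abs(t) < 4)

    def test_separated_feature_large_t(self):
        rng = np.random.default_rng(1)
        X = np.r_[np.zeros((10, 1)), np.ones((10, 1))] \
            + rng.normal(0, 1e-3, size=(20, 1))
        t = t_scores(X, labels(10, 10))
        assert t[0] < -100  # CA minus NC with CA = zeros

    def test_hand_computed(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        t = t_scores(X, labels(3, 3))  # CA {1,2,3} vs NC {4,5,6}
        assert t[0] == pytest.approx(-3.674, abs=1e-3)

    def test_zero_variance_warns_and_zeroes(self):
        X = np.ones((10, 1))
        with pytest.warns(UserWarning):
            t = t_scores(X, labels(5, 5))
        assert t[0] == 0.0


class TestShrinkageCorrelation:
    def test_independent_features_near_identity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(2000, 6))
        R, lam = shrinkage_correlation(X)
        off = R[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_duplicated_feature_shrunk_toward_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        X = np.c_[x, x + rng.normal(0, 0.01, 30)]
        R, lam = shrinkage_correlation(X)
        raw = np.corrcoef(X.T)[0, 1]
        assert 0 < R[0, 1] < raw
        assert 0 < lam < 1

    def test_agreement_with_bruteforce(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 5)) @ rng.normal(size=(5, 5))
        R, lam = shrinkage_correlation(X)
        R_o, lam_o = oracle_shrinkage(X)
        assert lam == pytest.approx(lam_o, rel=1e-10)
        np.testing.assert_allclose(R, R_o, atol=1e-10)

    def test_constant_feature_correlations_zero(self):
        rng = np.random.default_rng(5)
        X = np.c_[np.ones(20), rng.normal(size=(20, 2))]
        R, _ = shrinkage_correlation(X)
        assert R[0, 1] == 0.0 and R[0, 2] == 0.0


class TestCatScores:
    def test_identity_returns_t(self):
        t = np.array([1.0, -2.0, 0.5])
        np.testing.assert_allclose(cat_scores(t, np.eye(3)), t)

    def test_two_feature_symmetry(self):
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        tau = cat_scores(np.array([1.2, 1.2]), R)
        assert tau[0] == pytest.approx(tau[1], rel=1e-12)

    def test_against_bruteforce_matrix_root(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(3, 3))
        R = A @ A.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        t = rng.normal(size=3)
        expect = oracle_inv_sqrt(R) @ t
        np.testing.assert_allclose(cat_scores(t, R), expect, atol=1e-8)

    def test_ranking_deterministic_tiebreak(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 4))
        y = labels(15, 15)
        r1 = cat_ranking(X, y, ["d", "c", "b", "a"])
        r2 = cat_ranking(X, y, ["d", "c", "b", "a"])
        pd.testing.assert_frame_equal(r1, r2)
        assert sorted(r1["rank"]) == [1, 2, 3, 4]


class TestLda:
    def test_separated_clouds_perfect_training_accuracy(self):
        rng = np.random.default_rng(8)
        X = np.r_[rng.normal(0, 0.2, (20, 2)), rng.normal(5, 0.2, (20, 2))]
        y = labels(20, 20)
        model = fit_lda(X, y)
        assert ((model.scores(X) > 0) == (y == "CA")).mean() == 1.0

    def test_null_model_auc_half_on_heldout(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(400, 3))
        y = labels(200, 200)
        model = fit_lda(X[:200], y[np.r_[0:100, 200:300]])
        auc = auc_mann_whitney(model.scores(X[200:]),
                               y[np.r_[100:200, 300:400]])
        assert 0.4 < auc < 0.6

    def test_one_feature_closed_form(self):
        rng = np.random.default_rng(10)
        x1 = rng.normal(2.0, 1.0, 50)
        x0 = rng.normal(0.0, 1.0, 50)
        X = np.r_[x1, x0][:, None]
        y = labels(50, 50)
        model = fit_lda(X, y, ridge=0.0)
        n1, n0 = 50, 50
        s2 = ((n1 - 1) * x1.var(ddof=1) + (n0 - 1) * x0.var(ddof=1)) / 98
        expect = (x1.mean() - x0.mean()) / s2
        assert model.weights[0] == pytest.approx(expect, rel=1e-10)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(np.ones((3, 1)), np.array(["CA"] * 3))


class TestAuc:
    def test_enumeration_example(self):
        scores = np.array([0.9, 0.4, 0.7, 0.1])
        y = np.array(["CA", "CA", "NC", "NC"])
        assert auc_mann_whitney(scores, y) == 0.75
        assert oracle_auc(scores, y) == 0.75

    def test_perfect_separation(self):
        y = labels(5, 5)
        scores = np.r_[np.ones(5), np.zeros(5)]
        assert auc_mann_whitney(scores, y) == 1.0

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(-5, 5), min_size=4, max_size=12))
    def test_matches_pair_enumeration(self, vals):
        n = len(vals)
        y = np.array(["CA"] * (n // 2) + ["NC"] * (n - n // 2))
        scores = np.array(vals, float)
        assert auc_mann_whitney(scores, y) == pytest.approx(
            oracle_auc(scores, y), rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(-1000, 1000), min_size=6, max_size=12,
                    unique=True))
    def test_invariant_under_monotone_transform(self, vals):
        n = len(vals)
        y = np.array(["CA"] * (n // 2) + ["NC"] * (n - n // 2))
        s = np.array(vals, float) / 10.0
        a1 = auc_mann_whitney(s, y)
        a2 = auc_mann_whitney(np.exp(s / 50.0), y)
        assert a1 == pytest.approx(a2, rel=1e-9)


class TestCvAuc:
    def test_perfect_feature(self):
        rng = np.random.default_rng(11)
        X = np.r_[rng.normal(5, 0.1, (30, 1)), rng.normal(0, 0.1, (30, 1))]
        y = labels(30, 30)
        assert cv_auc(X, y, folds=5, seed=0)["auc"] == 1.0

    def test_label_permutation_null(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 2))
        aucs = []
        for rep in range(50):
            y = labels(30, 30)
            rng.shuffle(y)
            aucs.append(cv_auc(X, y, folds=5, seed=rep)["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_folds_stratified(self):
        y = labels(40, 20)
        fold = stratified_folds(y, 10, seed=1)
        for f in range(10):
            in_f = fold == f
            assert (y[in_f] == "CA").sum() == 4
            assert (y[in_f] == "NC").sum() == 2


class TestConfusionMetrics:
    def test_printed_cohort_example(self):
        m = confusion_metrics(tp=54, fn=4, fp=4, tn=53)
        assert round(100 * m["sensitivity"], 1) == 93.1
        assert round(100 * m["specificity"], 1) == 93.0
        assert round(100 * m["ppv"], 1) == 93.1
        assert round(100 * m["npv"], 1) == 93.0
        assert round(100 * m["accuracy"]) == 93

    def test_perfect(self):
        m = confusion_metrics(tp=10, fn=0, fp=0, tn=10)
        assert m["sensitivity"] == m["specificity"] == m["accuracy"] == 1.0

    def test_empty_denominators_nan(self):
        m = confusion_metrics(tp=0, fn=0, fp=0, tn=5)
        assert np.isnan(m["sensitivity"])


def make_stack(X, m_copies=3, columns=None):
    cols = columns or [f"g{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=cols)
    copies = [df.copy() for _ in range(m_copies)]
    mask = pd.DataFrame(False, index=df.index, columns=cols)
    return ImputedStack(copies, mask, ImputationConfig(m_copies=m_copies))


class TestSelectAndTrain:
    def test_deterministic_feature_always_selected(self):
        rng = np.random.default_rng(13)
        n = 60
        y = labels(30, 30)
        X = rng.normal(size=(n, 6))
        X[:30, 0] += 4.0  # strongly informative
        stack = make_stack(X)
        res = select_and_train(stack, y, k_grid=[1, 2, 3], folds=5, seed=2)
        assert res.vote_fractions["g0"] == 1.0
        assert "g0" in res.final_features

    def test_null_data_honest_auc_calibrated(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(80, 10))
            y = labels(40, 40)
            stack = make_stack(X, m_copies=2)
            res = select_and_train(stack, y, k_grid=[2, 5], folds=5,
                                   seed=seed, mode="honest")
            aucs.append(res.k_results["avg_auc"].mean())
        assert 0.4 < np.mean(aucs) < 0.6

    def test_full_mode_optimistic_on_null(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(60, 40))
        y = labels(30, 30)
        stack = make_stack(X, m_copies=2)
        honest = select_and_train(stack, y, k_grid=[5], folds=5, seed=3,
                                  mode="honest")
        full = select_and_train(stack, y, k_grid=[5], folds=5, seed=3,
                                mode="full")
        assert full.k_results["avg_auc"].iloc[0] > \
            honest.k_results["avg_auc"].iloc[0]

    def test_best_k_maximizes_avg_auc(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(60, 8))
        X[:30, :2] += 1.5
        y = labels(30, 30)
        stack = make_stack(X)
        res = select_and_train(stack, y, k_grid=[1, 2, 4, 8], folds=5, seed=4)
        best_row = res.k_results.loc[res.k_results["avg_auc"].idxmax()]
        assert res.best_k == best_row["k"]

    def test_selected_features_meet_vote_threshold(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(60, 6))
        X[:30, 0] += 3.0
        y = labels(30, 30)
        stack = make_stack(X)
        res = select_and_train(stack, y, k_grid=[2, 3], folds=5, seed=5,
                               vote_threshold=0.6)
        for f in res.final_features:
            assert res.vote_fractions[f] >= 0.6

    def test_end_to_end_jaccard_recovery(self):
        """Selected features overlap truth (Jaccard >= 0.6) under strong
        effects, across seeds, through impute + select."""
        from compseq.simulate import SimConfig, generate_cohort
        jaccards = []
        for seed in range(5):
            cfg = SimConfig(n_subjects_cancer=58, n_subjects_control=57,
                            n_assays=20, n_genes=10, n_informative_assays=8,
                            effect_size_log10=0.5, seed=300 + seed)
            subjects, truth = generate_cohort(cfg)
            log10 = np.log10(truth.abundance)
            # MCAR missingness, then impute
            rng = np.random.default_rng(seed)
            vals = log10.copy()
            genes = [a for a in vals.columns
                     if truth.assay_info.at[a, "gene"] != "ACTB"]
            vals = vals[genes]
            drop = rng.random(vals.shape) < 0.1
            vals = vals.mask(drop)
            stack = mice_pmm(vals, ImputationConfig(
                m_copies=3, n_chained_iterations=3, seed=seed))
            y = subjects["class_label"].to_numpy()
            res = select_and_train(stack, y, k_grid=range(2, 13), folds=5,
                                   seed=seed)
            true_set = set(truth.assay_info.index[
                truth.assay_info.informative])
            sel = set(res.final_features)
            jaccards.append(len(sel & true_set) / len(sel | true_set))
        assert np.mean(jaccards) >= 0.6

    def test_bad_k_grid_rejected(self):
        rng = np.random.default_rng(17)
        stack = make_stack(rng.normal(size=(20, 3)))
        with pytest.raises(ValueError):
            select_and_train(stack, labels(10, 10), k_grid=[5])


class TestEvaluate:
    def _trained(self, seed=18):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(80, 5))
        X[:40, 0] += 2.5
        y = labels(40, 40)
        stack = make_stack(X)
        res = select_and_train(stack, y, k_grid=[1, 2], folds=5, seed=seed)
        return res, stack, y

    def test_report_fields(self):
        res, stack, y = self._trained()
        rep = evaluate(res, stack, y, stack.mask.mean())
        assert rep.auc.point > 0.8
        assert (rep.roc["tpr"].diff().dropna() >= 0).all()
        assert (rep.roc["fpr"].diff().dropna() >= 0).all()
        assert set(rep.feature_table["feature"]) == set(res.feature_names)

    def test_metrics_consistent_with_confusion(self):
        res, stack, y = self._trained()
        rep = evaluate(res, stack, y)
        cm = rep.confusion
        assert cm["sensitivity"] == pytest.approx(
            cm["tp"] / (cm["tp"] + cm["fn"]))

    def test_perfect_scores_give_full_specificity_at_95(self):
        rng = np.random.default_rng(19)
        X = np.r_[rng.normal(8, 0.1, (30, 1)), rng.normal(0, 0.1, (30, 1))]
        y = labels(30, 30)
        stack = make_stack(X)
        res = select_and_train(stack, y, k_grid=[1], folds=5, seed=20)
        rep = evaluate(res, stack, y)
        assert rep.specificity_at_sensitivity == 1.0
        assert rep.auc.point == 1.0


class TestCompareModels:
    def _report_from_scores(self, scores, y):
        res, stack, yy = None, None, None
        rng = np.random.default_rng(0)
        X = np.asarray(scores, float)[:, None]
        stack = make_stack(X, m_copies=2)
        res = select_and_train(stack, y, k_grid=[1], folds=5, seed=21)
        rep = evaluate(res, stack, y)
        # overwrite mean scores with the requested vector for a pure
        # score-level comparison
        rep.mean_scores = np.asarray(scores, float)
        return rep

    def test_identical_scores_no_difference(self):
        rng = np.random.default_rng(22)
        y = labels(30, 30)
        s = rng.normal(size=60)
        r1 = self._report_from_scores(s, y)
        r2 = self._report_from_scores(s, y)
        out = compare_models(r1, r2, n_boot=500, seed=1)
        assert out["auc_difference"] == 0.0
        assert out["p_value"] > 0.5

    def test_extreme_separation_significant(self):
        y = labels(58, 57)
        perfect = np.r_[np.ones(58), np.zeros(57)]
        rng = np.random.default_rng(23)
        noise = rng.normal(size=115)
        r1 = self._report_from_scores(perfect, y)
        r2 = self._report_from_scores(noise, y)
        out = compare_models(r1, r2, n_boot=1000, seed=2)
        assert out["auc_full"] == 1.0
        assert out["p_value"] < 0.01

    def test_known_gap_power(self):
        """AUC gap ~0.2 at n=115 detected at alpha=0.05 in >=80% of repeats."""
        hits = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(3000 + rep)
            y = labels(58, 57)
            pos = y == "CA"
            # scores built to give population AUCs ~0.95 and ~0.75
            s1 = np.where(pos, rng.normal(2.33, 1, 115), rng.normal(0, 1, 115))
            s2 = np.where(pos, rng.normal(0.95, 1, 115), rng.normal(0, 1, 115))
            r1 = self._report_from_scores(s1, y)
            r2 = self._report_from_scores(s2, y)
            out = compare_models(r1, r2, n_boot=400, seed=rep)
            if out["p_value"] < 0.05:
                hits += 1
        assert hits >= 0.8 * reps

    def test_mismatched_subjects_rejected(self):
        rng = np.random.default_rng(24)
        y1, y2 = labels(30, 30), labels(29, 31)
        r1 = self._report_from_scores(rng.normal(size=60), y1)
        r2 = self._report_from_scores(rng.normal(size=60), y2)
        with pytest.raises(ValueError):
            compare_models(r1, r2)


class TestRubinReduction:
    def test_identical_copies_reduce_to_single_estimate(self):
        rng = np.random.default_rng(25)
        X = rng.normal(size=(60, 4))
        X[:30, 0] += 2
        y = labels(30, 30)
        stack = make_stack(X, m_copies=4)
        res = select_and_train(stack, y, k_grid=[1, 2], folds=5, seed=26)
        # copies identical -> between-imputation variance is zero
        assert res.pooled["auc"].between_var == 0.0
        assert res.pooled["auc"].point == pytest.approx(
            auc_mann_whitney(res.oof_scores[:, 0], y))
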