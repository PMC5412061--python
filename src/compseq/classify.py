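"""Correlation-adjusted t-score feature ranking, vote-based selection
across imputed copies, per-copy LDA with stratified 10-fold CV, model-size
search by average AUC, and pooled performance reporting.

Scores follow the convention positive-class (CA) minus negative-class (NC);
feature ranking ties break by feature name for determinism. The default
"honest" mode recomputes ranking and voting inside every training fold, so
null data cross-validate to AUC ~ 0.5; "full" mode (rank once on all rows,
as a paper-style analysis would) is optimistically biased and flagged as
such.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .impute import ImputedStack, PooledEstimate, rubin_pool

POSITIVE = "CA"
NEGATIVE = "NC"


# ---------------------------------------------------------------------------
# scores and rankings
# ---------------------------------------------------------------------------

def t_scores(X: np.ndarray, y: np.ndarray,
             positive: str = POSITIVE) -> np.ndarray:
    """Two-sample pooled-variance t per feature (positive minus negative).

    Zero-variance features get t = 0 with a warning.
    """
    pos = y == positive
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("both classes need at least 2 subjects")
    X1, X0 = X[pos], X[~pos]
    diff = X1.mean(axis=0) - X0.mean(axis=0)
    sp2 = ((n1 - 1) * X1.var(axis=0, ddof=1)
           + (n0 - 1) * X0.var(axis=0, ddof=1)) / (n1 + n0 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    zero = denom == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance feature(s); t set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(zero, 0.0, diff / np.where(zero, 1.0, denom))
    return t


def shrinkage_correlation(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Sample correlation shrunk toward the identity.

    The shrinkage intensity is the analytic variance-over-squared-entries
    estimator (sum of estimated variances of the off-diagonal correlations
    over their sum of squares), clipped to [0, 1]. Constant features
    contribute zero correlations.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need n >= 3 to estimate shrinkage intensity")
    sd = X.std(axis=0, ddof=1)
    ok = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    R = Xs.T @ Xs / (n - 1)
    np.fill_diagonal(R, 1.0)

    # var-hat of each r_ij from the empirical variance of the products
    W_mean = R * (n - 1) / n  # mean over k of w_kij = xs_ki * xs_kj
    sq = (Xs ** 2).T @ (Xs ** 2) / n  # mean over k of w_kij^2
    var_w = sq - W_mean ** 2
    var_r = n / (n - 1) ** 3 * n * var_w  # n/(n-1)^3 * sum_k (w - wbar)^2
    off = ~np.eye(p, dtype=bool)
    denom = float((R[off] ** 2).sum())
    lam = 1.0 if denom == 0 else float(np.clip(var_r[off].sum() / denom, 0, 1))
    R_shrunk = (1.0 - lam) * R
    np.fill_diagonal(R_shrunk, 1.0)
    return R_shrunk, lam


def cat_scores(t: np.ndarray, R: np.ndarray,
               eps: float = 1e-8) -> np.ndarray:
    """Decorrelated t: tau = R^(-1/2) t via eigendecomposition.

    Eigenvalues are floored at ``eps`` before inversion.
    """
    R = np.asarray(R, float)
    vals, vecs = np.linalg.eigh((R + R.T) / 2)
    vals = np.maximum(vals, eps)
    inv_sqrt = vecs @ np.diag(vals ** -0.5) @ vecs.T
    return inv_sqrt @ np.asarray(t, float)


def cat_ranking(X: np.ndarray, y: np.ndarray,
                feature_names: Sequence[str]) -> pd.DataFrame:
    """Per-feature t, CAT score, and rank (1 = largest |CAT|)."""
    t = t_scores(X, y)
    R, lam = shrinkage_correlation(X)
    tau = cat_scores(t, R)
    df = pd.DataFrame({"feature": list(feature_names),
                       "t_score": t, "cat_score": tau})
    df["abs_cat"] = df["cat_score"].abs()
    df = df.sort_values(["abs_cat", "feature"],
                        ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs["shrinkage_lambda"] = lam
    return df.drop(columns="abs_cat").reset_index(drop=True)


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LdaModel:
    features: list[str]
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    weights: np.ndarray
    threshold: float
    ridge: float

    def scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights - self.threshold

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.scores(X) > 0

    def to_dict(self) -> dict:
        return {"features": self.features,
                "weights": self.weights.tolist(),
                "threshold": self.threshold,
                "mean_pos": self.mean_pos.tolist(),
                "mean_neg": self.mean_neg.tolist()}


def fit_lda(X: np.ndarray, y: np.ndarray,
            feature_names: Optional[Sequence[str]] = None,
            ridge: float = 1e-6, positive: str = POSITIVE) -> LdaModel:
    """Pooled-covariance LDA: w = Sigma^-1 (mu_pos - mu_neg).

    Equal class priors; the decision threshold sits at the midpoint of the
    projected class means. Ridge (scaled by the mean diagonal) keeps the
    pooled covariance invertible when p approaches n.
    """
    X = np.asarray(X, float)
    pos = y == positive
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    mu1 = X[pos].mean(axis=0)
    mu0 = X[~pos].mean(axis=0)
    p = X.shape[1]
    if n1 + n0 - 2 < 1:
        raise ValueError("too few subjects for a pooled covariance")
    S1 = np.cov(X[pos], rowvar=False, ddof=1) if n1 > 1 else np.zeros((p, p))
    S0 = np.cov(X[~pos], rowvar=False, ddof=1) if n0 > 1 else np.zeros((p, p))
    S1 = np.atleast_2d(S1)
    S0 = np.atleast_2d(S0)
    cov = ((n1 - 1) * S1 + (n0 - 1) * S0) / (n1 + n0 - 2)
    scale = max(float(np.trace(cov)) / p, 1e-12)
    cov_r = cov + ridge * scale * np.eye(p)
    try:
        w = np.linalg.solve(cov_r, mu1 - mu0)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular pooled covariance; increase ridge") from exc
    thr = float(w @ (mu1 + mu0) / 2.0)
    names = list(feature_names) if feature_names is not None else \
        [f"f{i}" for i in range(p)]
    return LdaModel(names, mu1, mu0, w, thr, ridge)


# ---------------------------------------------------------------------------
# AUC and cross-validation
# ---------------------------------------------------------------------------

def auc_mann_whitney(scores: np.ndarray, y: np.ndarray,
                     positive: str = POSITIVE) -> float:
    """Rank-based AUC with midrank tie correction."""
    pos = y == positive
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def stratified_folds(y: np.ndarray, folds: int,
                     seed: int) -> np.ndarray:
    """Fold labels 0..folds-1, class-balanced, seeded."""
    rng = np.random.default_rng(seed)
    assign = np.empty(len(y), int)
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        idx = rng.permutation(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


def cv_auc(X: np.ndarray, y: np.ndarray,
           feature_idx: Optional[Sequence[int]] = None,
           folds: int = 10, seed: int = 0,
           fold_assign: Optional[np.ndarray] = None,
           ridge: float = 1e-6) -> dict:
    """Stratified k-fold CV of an LDA on the given features.

    Held-out discriminant scores from all folds are pooled into one AUC.
    """
    X = np.asarray(X, float)
    if feature_idx is not None:
        X = X[:, list(feature_idx)]
    if fold_assign is None:
        fold_assign = stratified_folds(y, folds, seed)
    oof = np.empty(len(y))
    for f in np.unique(fold_assign):
        train = fold_assign != f
        if len(np.unique(y[train])) < 2:
            raise ValueError("training fold lost a class; use fewer folds")
        model = fit_lda(X[train], y[train], ridge=ridge)
        oof[~train] = model.scores(X[~train])
    return {"oof_scores": oof, "auc": auc_mann_whitney(oof, y),
            "fold_assign": fold_assign}


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion_metrics(tp: int, fn: int, fp: int, tn: int) -> dict:
    """Sensitivity/specificity/PPV/NPV/accuracy from a confusion matrix.

    Fractions in [0, 1]; undefined ratios are NaN.
    """
    def ratio(a, b):
        return a / b if b > 0 else math.nan

    return {"tp": tp, "fn": fn, "fp": fp, "tn": tn,
            "sensitivity": ratio(tp, tp + fn),
            "specificity": ratio(tn, tn + fp),
            "ppv": ratio(tp, tp + fp),
            "npv": ratio(tn, tn + fn),
            "accuracy": ratio(tp + tn, tp + fn + fp + tn)}


def _confusion_from_scores(scores: np.ndarray, y: np.ndarray,
                           threshold: float = 0.0,
                           positive: str = POSITIVE) -> dict:
    pred = scores > threshold
    pos = y == positive
    return confusion_metrics(int((pred & pos).sum()),
                             int((~pred & pos).sum()),
                             int((pred & ~pos).sum()),
                             int((~pred & ~pos).sum()))


def _auc_variance_hanley(auc: float, n1: int, n0: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    v = (auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2)
         + (n0 - 1) * (q2 - auc ** 2)) / (n1 * n0)
    return max(v, 0.0)


def roc_points(scores: np.ndarray, y: np.ndarray,
               positive: str = POSITIVE) -> pd.DataFrame:
    """ROC curve (fpr, tpr, threshold), non-decreasing in both axes."""
    pos = y == positive
    n1, n0 = int(pos.sum()), int((~pos).sum())
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(pos[order])
    fps = np.cumsum(~pos[order])
    # collapse tied thresholds
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    tps, fps = tps[distinct], fps[distinct]
    thr = scores[order][distinct]
    return pd.DataFrame({
        "fpr": np.r_[0.0, fps / n0], "tpr": np.r_[0.0, tps / n1],
        "threshold": np.r_[np.inf, thr]})


# ---------------------------------------------------------------------------
# model search over imputed copies
# ---------------------------------------------------------------------------

@dataclass
class ModelSearchResult:
    k_grid: list[int]
    k_results: pd.DataFrame  # per k: avg_auc, avg_accuracy, n_selected
    best_k: int
    final_features: list[str]
    vote_fractions: pd.Series  # at best_k, from full-data voting
    oof_scores: np.ndarray  # subjects x M, out-of-fold scores at best_k
    per_copy_auc: np.ndarray
    pooled: dict[str, PooledEstimate]
    fold_assign: np.ndarray
    mode: str
    models: list[LdaModel] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    subject_index: Optional[pd.Index] = None

    def to_dict(self) -> dict:
        return {
            "best_k": self.best_k,
            "mode": self.mode,
            "final_features": self.final_features,
            "vote_fractions": {k: float(v)
                               for k, v in self.vote_fractions.items()},
            "k_results": self.k_results.to_dict(orient="records"),
            "pooled": {k: vars(v) for k, v in self.pooled.items()},
            "models": [m.to_dict() for m in self.models],
        }


def _rank_order(X: np.ndarray, y: np.ndarray, names: list[str]) -> list[int]:
    """Feature indices ordered by |CAT| descending, name-tiebroken."""
    t = t_scores(X, y)
    R, _ = shrinkage_correlation(X)
    tau = np.abs(cat_scores(t, R))
    return sorted(range(len(names)), key=lambda j: (-tau[j], names[j]))


def _per_copy_metrics(oof: np.ndarray, y: np.ndarray) -> dict:
    n1 = int((y == POSITIVE).sum())
    n0 = len(y) - n1
    auc = auc_mann_whitney(oof, y)
    cm = _confusion_from_scores(oof, y)
    out = {"auc": (auc, _auc_variance_hanley(auc, n1, n0))}
    for key, n in (("sensitivity", n1), ("specificity", n0),
                   ("ppv", cm["tp"] + cm["fp"]), ("npv", cm["tn"] + cm["fn"]),
                   ("accuracy", len(y))):
        p = cm[key]
        var = p * (1 - p) / n if (n > 0 and not math.isnan(p)) else math.nan
        out[key] = (p, var)
    return out


def select_and_train(stack: ImputedStack, y: np.ndarray,
                     k_grid: Optional[Sequence[int]] = None,
                     vote_threshold: float = 0.60,
                     folds: int = 10, seed: int = 0,
                     mode: str = "honest",
                     feature_subset: Optional[Sequence[str]] = None,
                     ridge: float = 1e-6) -> ModelSearchResult:
    """Model-size search: vote-based feature selection + per-copy CV LDA.

    For each candidate size k, a feature is "voted" by an imputed copy when
    it ranks in that copy's top k by |CAT|; features with vote fraction >=
    ``vote_threshold`` form the candidate set, which is evaluated by
    stratified k-fold CV LDA on each copy. best_k maximizes the average
    AUC across copies (ties -> smaller k). In honest mode ranking/voting
    happen inside each training fold; in "full" mode they use all rows.
    """
    if mode not in ("honest", "full"):
        raise ValueError("mode must be 'honest' or 'full'")
    y = np.asarray(y)
    copies = stack.copies
    if feature_subset is not None:
        copies = [c[list(feature_subset)] for c in copies]
    names = list(copies[0].columns)
    p = len(names)
    n = len(y)
    M = len(copies)
    if k_grid is None:
        k_grid = range(1, min(26, p + 1))
    k_grid = sorted(set(int(k) for k in k_grid))
    if any(k < 1 or k > p for k in k_grid):
        raise ValueError("k_grid entries must lie in 1..p")

    fold_assign = stratified_folds(y, folds, seed)
    fold_ids = np.unique(fold_assign)
    mats = [c.to_numpy(float) for c in copies]

    # rank orders reused across the whole k grid
    if mode == "honest":
        orders = {}
        for m in range(M):
            for f in fold_ids:
                train = fold_assign != f
                orders[(m, f)] = _rank_order(mats[m][train], y[train], names)
    else:
        full_orders = [_rank_order(mats[m], y, names) for m in range(M)]

    rows = []
    best = None
    for k in k_grid:
        if mode == "full":
            votes = np.zeros(p)
            for m in range(M):
                votes[full_orders[m][:k]] += 1
            sel = np.where(votes / M >= vote_threshold)[0]
            if len(sel) == 0:
                warnings.warn(f"k={k}: empty candidate set, skipped")
                continue
            sel_per_fold = {f: sel for f in fold_ids}
        else:
            sel_per_fold = {}
            empty = False
            for f in fold_ids:
                votes = np.zeros(p)
                for m in range(M):
                    votes[orders[(m, f)][:k]] += 1
                sel = np.where(votes / M >= vote_threshold)[0]
                if len(sel) == 0:
                    empty = True
                    break
                sel_per_fold[f] = sel
            if empty:
                warnings.warn(f"k={k}: empty candidate set in a fold, skipped")
                continue

        oof = np.empty((n, M))
        aucs = np.empty(M)
        accs = np.empty(M)
        for m in range(M):
            Xm = mats[m]
            for f in fold_ids:
                train = fold_assign != f
                sel = sel_per_fold[f]
                model = fit_lda(Xm[np.ix_(train, sel)], y[train], ridge=ridge)
                oof[~train, m] = model.scores(Xm[np.ix_(~train, sel)])
            aucs[m] = auc_mann_whitney(oof[:, m], y)
            accs[m] = _confusion_from_scores(oof[:, m], y)["accuracy"]
        n_sel = int(np.mean([len(s) for s in sel_per_fold.values()]))
        rows.append({"k": k, "avg_auc": float(aucs.mean()),
                     "avg_accuracy": float(accs.mean()),
                     "n_selected": n_sel})
        if best is None or rows[-1]["avg_auc"] > best["avg_auc"] + 1e-12:
            best = {"k": k, "avg_auc": rows[-1]["avg_auc"],
                    "oof": oof, "aucs": aucs}

    if best is None:
        raise ValueError("no model size produced a non-empty candidate set")
    k_results = pd.DataFrame(rows)

    # final reported feature set: full-data voting at best_k
    full_orders_final = [_rank_order(mats[m], y, names) for m in range(M)]
    votes = np.zeros(p)
    for m in range(M):
        votes[full_orders_final[m][: best["k"]]] += 1
    vote_frac = pd.Series(votes / M, index=names)
    final_idx = np.where(vote_frac.to_numpy() >= vote_threshold)[0]
    final_features = [names[j] for j in final_idx]

    models = [fit_lda(mats[m][:, final_idx], y,
                      feature_names=final_features, ridge=ridge)
              for m in range(M)] if len(final_idx) else []

    per_copy = [_per_copy_metrics(best["oof"][:, m], y) for m in range(M)]
    pooled = {}
    for key in ("auc", "sensitivity", "specificity", "ppv", "npv", "accuracy"):
        ests = [pc[key][0] for pc in per_copy]
        vars_ = [pc[key][1] for pc in per_copy]
        if any(math.isnan(e) or math.isnan(v) for e, v in zip(ests, vars_)):
            continue
        pooled[key] = rubin_pool(ests, vars_)

    return ModelSearchResult(
        k_grid=list(k_grid), k_results=k_results, best_k=best["k"],
        final_features=final_features, vote_fractions=vote_frac,
        oof_scores=best["oof"], per_copy_auc=best["aucs"], pooled=pooled,
        fold_assign=fold_assign, mode=mode, models=models,
        feature_names=names, subject_index=copies[0].index)


# ---------------------------------------------------------------------------
# evaluation and comparison
# ---------------------------------------------------------------------------

@dataclass
class PerformanceReport:
    roc: pd.DataFrame
    auc: PooledEstimate
    metrics: dict[str, PooledEstimate]
    confusion: dict
    threshold_for_sensitivity: float
    specificity_at_sensitivity: float
    target_sensitivity: float
    feature_table: pd.DataFrame
    mean_scores: np.ndarray
    y: np.ndarray
    subject_index: Optional[pd.Index] = None

    def to_dict(self) -> dict:
        return {
            "auc": vars(self.auc),
            "metrics": {k: vars(v) for k, v in self.metrics.items()},
            "confusion": self.confusion,
            "target_sensitivity": self.target_sensitivity,
            "specificity_at_target_sensitivity":
                self.specificity_at_sensitivity,
            "feature_table": self.feature_table.to_dict(orient="records"),
        }


def evaluate(result: ModelSearchResult, stack: ImputedStack, y: np.ndarray,
             missing_fraction: Optional[pd.Series] = None,
             target_sensitivity: float = 0.95) -> PerformanceReport:
    """Pooled ROC/metrics plus a feature table (rank, vote share, missing %).

    The ROC and the sensitivity-constrained operating point use each
    subject's out-of-fold score averaged over the M copies.
    """
    y = np.asarray(y)
    mean_scores = result.oof_scores.mean(axis=1)
    roc = roc_points(mean_scores, y)
    cm = _confusion_from_scores(mean_scores, y)

    # smallest threshold achieving the target cross-validated sensitivity
    ok = roc["tpr"] >= target_sensitivity
    if ok.any():
        row = roc[ok].iloc[0]
        thr95 = float(row["threshold"])
        spec95 = 1.0 - float(row["fpr"])
    else:
        thr95, spec95 = -math.inf, 0.0

    # feature table: rank by mean |CAT| over copies on full data
    names = result.feature_names
    abs_cat = np.zeros(len(names))
    for copy in stack.copies:
        Xm = copy[names].to_numpy(float)
        t = t_scores(Xm, y)
        R, _ = shrinkage_correlation(Xm)
        abs_cat += np.abs(cat_scores(t, R))
    abs_cat /= stack.m
    table = pd.DataFrame({"feature": names, "mean_abs_cat": abs_cat,
                          "selection_frequency":
                              result.vote_fractions.reindex(names).to_numpy()})
    if missing_fraction is not None:
        table["missing_fraction"] = missing_fraction.reindex(names).to_numpy()
    table = table.sort_values(["mean_abs_cat", "feature"],
                              ascending=[False, True], kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    table = table.reset_index(drop=True)

    pooled_auc = result.pooled.get("auc")
    if pooled_auc is None:
        n1 = int((y == POSITIVE).sum())
        a = auc_mann_whitney(mean_scores, y)
        v = _auc_variance_hanley(a, n1, len(y) - n1)
        pooled_auc = rubin_pool([a, a], [v, v])
    return PerformanceReport(
        roc=roc, auc=pooled_auc,
        metrics={k: v for k, v in result.pooled.items() if k != "auc"},
        confusion=cm, threshold_for_sensitivity=thr95,
        specificity_at_sensitivity=spec95,
        target_sensitivity=target_sensitivity,
        feature_table=table, mean_scores=mean_scores, y=y,
        subject_index=result.subject_index)


def compare_models(report_full: PerformanceReport,
                   report_reduced: PerformanceReport,
                   n_boot: int = 2000, seed: int = 0) -> dict:
    """Paired bootstrap over subjects for the AUC difference.

    Both reports must score the same subjects in the same order.
    """
    if len(report_full.y) != len(report_reduced.y) or \
            not np.array_equal(report_full.y, report_reduced.y):
        raise ValueError("reports cover different subject sets")
    if (report_full.subject_index is not None
            and report_reduced.subject_index is not None
            and not report_full.subject_index.equals(
                report_reduced.subject_index)):
        raise ValueError("reports cover different subject sets")
    y = report_full.y
    s1, s2 = report_full.mean_scores, report_reduced.mean_scores
    a1 = auc_mann_whitney(s1, y)
    a2 = auc_mann_whitney(s2, y)
    obs = a1 - a2
    rng = np.random.default_rng(seed)
    n = len(y)
    diffs = np.empty(n_boot)
    kept = 0
    for b in range(n_boot):
        idx = rng.integers(n, size=n)
        yb = y[idx]
        if len(np.unique(yb)) < 2:
            continue
        diffs[kept] = (auc_mann_whitney(s1[idx], yb)
                       - auc_mann_whitney(s2[idx], yb))
        kept += 1
    diffs = diffs[:kept]
    # percentile bootstrap p-value for H0: difference == 0
    frac_le = (np.sum(diffs <= 0) + 1) / (kept + 1)
    frac_ge = (np.sum(diffs >= 0) + 1) / (kept + 1)
    p = min(1.0, 2.0 * min(frac_le, frac_ge))
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return {"auc_full": a1, "auc_reduced": a2, "auc_difference": obs,
            "ci_low": float(lo), "ci_high": float(hi),
            "p_value": float(p), "n_bootstrap": kept}


def write_report(report: PerformanceReport, json_path,
                 roc_path=None, feature_table_path=None) -> None:
    from pathlib import Path
    Path(json_path).write_text(json.dumps(report.to_dict(), indent=2))
    if roc_path is not None:
        report.roc.to_csv(roc_path, sep="\t", index=False)
    if feature_table_path is not None:
        report.feature_table.to_csv(feature_table_path, sep="\t", index=False)
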