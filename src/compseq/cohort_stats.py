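"""Cohort summary statistics: per-class means, Student's t-tests for
continuous variables, and exact tests for categorical variables.

The Fisher exact p-value is two-sided by the "no more probable" rule:
the sum of probabilities of all tables with the observed margins whose
probability does not exceed that of the observed table. 2x2 tables use
hypergeometric enumeration; r x c tables are enumerated exhaustively when
the total is <= 200, else a seeded Monte Carlo approximation is used.
"""

from __future__ import annotations

import math
from itertools import product
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

_REL_TOL = 1.0 + 1e-7  # guards float noise in "no more probable" comparisons


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table via hypergeometric pmf."""
    (a, b), (c, d) = np.asarray(table, int)
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = stats.hypergeom.pmf(a, n, c1, r1)
    return float(pmf[pmf <= p_obs * _REL_TOL].sum())


def _log_table_prob(table: np.ndarray, log_fact: np.ndarray) -> float:
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    lp = (log_fact[rows].sum() + log_fact[cols].sum() - log_fact[n]
          - log_fact[table.ravel()].sum())
    return float(lp)


def _enumerate_tables(rows: np.ndarray, cols: np.ndarray):
    """All non-negative integer tables with the given margins."""
    r, c = len(rows), len(cols)

    def rec(i: int, remaining_cols: np.ndarray):
        if i == r - 1:
            if (remaining_cols >= 0).all() and remaining_cols.sum() == rows[i]:
                yield [tuple(remaining_cols)]
            return
        ranges = [range(min(rows[i], remaining_cols[j]) + 1)
                  for j in range(c - 1)]
        for head in product(*ranges):
            last = rows[i] - sum(head)
            if last < 0 or last > remaining_cols[c - 1]:
                continue
            row = np.array(head + (last,))
            for rest in rec(i + 1, remaining_cols - row):
                yield [tuple(row)] + rest

    yield from rec(0, cols.copy())


def fisher_exact_rxc(table, max_exact_total: int = 200,
                     n_sim: int = 20000, seed: int = 0) -> float:
    """Two-sided exact (or simulated) test for an r x c table."""
    obs = np.asarray(table, int)
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape == (2, 2):
        return fisher_exact_2x2(obs)
    if min(obs.shape) < 2:
        return 1.0
    n = int(obs.sum())
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    log_fact = np.array([math.lgamma(k + 1) for k in range(n + 1)])
    lp_obs = _log_table_prob(obs, log_fact)
    if n <= max_exact_total:
        p = 0.0
        for tab in _enumerate_tables(rows, cols):
            t = np.array(tab)
            lp = _log_table_prob(t, log_fact)
            if lp <= lp_obs + math.log(_REL_TOL):
                p += math.exp(lp)
        return min(p, 1.0)
    # Monte Carlo: permute category labels, count tables no more probable
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(len(rows)), rows)
    col_labels = np.repeat(np.arange(len(cols)), cols)
    hits = 0
    for _ in range(n_sim):
        perm = rng.permutation(col_labels)
        t = np.zeros_like(obs)
        np.add.at(t, (row_labels, perm), 1)
        if _log_table_prob(t, log_fact) <= lp_obs + math.log(_REL_TOL):
            hits += 1
    return (hits + 1) / (n_sim + 1)


def summarize_cohort(subjects: pd.DataFrame,
                     continuous: tuple[str, ...] = ("age", "pack_years"),
                     categorical: tuple[str, ...] = ("gender",),
                     equal_var: bool = True,
                     seed: int = 0) -> pd.DataFrame:
    """Per-class descriptive statistics with p-values.

    Continuous variables: mean (+/- SD) per class and a two-sample
    Student's t-test (Welch with ``equal_var=False``). Categorical
    variables: per-class counts and an exact test. Missing values are
    excluded per variable; the reported denominators are explicit.
    """
    classes = sorted(subjects["class_label"].dropna().unique())
    if len(classes) != 2:
        raise ValueError("cohort summary requires exactly two classes")
    for cls in classes:
        if (subjects["class_label"] == cls).sum() < 2:
            raise ValueError(f"class {cls} has fewer than 2 subjects")
    rows = []
    for var in continuous:
        if var not in subjects:
            continue
        groups = [subjects.loc[subjects["class_label"] == c, var].dropna()
                  for c in classes]
        t, p = stats.ttest_ind(groups[0], groups[1], equal_var=equal_var)
        rows.append({
            "variable": var, "type": "continuous",
            f"{classes[0]}_summary":
                f"{groups[0].mean():.1f} (+/-{groups[0].std(ddof=1):.1f})",
            f"{classes[1]}_summary":
                f"{groups[1].mean():.1f} (+/-{groups[1].std(ddof=1):.1f})",
            f"{classes[0]}_n": len(groups[0]),
            f"{classes[1]}_n": len(groups[1]),
            "p_value": float(p)})
    for var in categorical:
        if var not in subjects:
            continue
        sub = subjects[["class_label", var]].dropna()
        tab = pd.crosstab(sub[var], sub["class_label"])
        tab = tab.reindex(columns=classes, fill_value=0)
        p = fisher_exact_rxc(tab.to_numpy(), seed=seed)
        rows.append({
            "variable": var, "type": "categorical",
            f"{classes[0]}_summary": "/".join(
                f"{idx}:{tab.at[idx, classes[0]]}" for idx in tab.index),
            f"{classes[1]}_summary": "/".join(
                f"{idx}:{tab.at[idx, classes[1]]}" for idx in tab.index),
            f"{classes[0]}_n": int(tab[classes[0]].sum()),
            f"{classes[1]}_n": int(tab[classes[1]].sum()),
            "p_value": float(p)})
    return pd.DataFrame(rows)
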