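"""Multiple imputation by chained equations with predictive mean matching,
and Rubin's-rules pooling.

Each of the M copies is imputed independently: missing cells start as
random draws from the observed marginal, then chained regression sweeps
(with Bayesian parameter draws, so the imputation is proper) predict each
incomplete feature from all others and fill every missing cell with the
observed value of a donor sampled among the k nearest predicted means.
Imputed values are therefore always elements of the observed support.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ImputationConfig:
    m_copies: int = 50
    n_chained_iterations: int = 10
    k_donors: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.m_copies < 2:
            raise ValueError("m_copies must be >= 2")
        if self.k_donors < 1:
            raise ValueError("k_donors must be >= 1")
        if self.n_chained_iterations < 1:
            raise ValueError("n_chained_iterations must be >= 1")


@dataclass
class ImputedStack:
    """M completed copies of a feature matrix plus the missingness mask."""

    copies: list[pd.DataFrame]
    mask: pd.DataFrame  # True where the input was missing
    config: ImputationConfig

    @property
    def m(self) -> int:
        return len(self.copies)

    def write(self, directory, stem: str = "imputed") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, copy in enumerate(self.copies, start=1):
            copy.to_csv(directory / f"{stem}_{i:03d}.tsv", sep="\t")
        manifest = {
            "m_copies": self.m,
            "seed": self.config.seed,
            "n_chained_iterations": self.config.n_chained_iterations,
            "k_donors": self.config.k_donors,
            "missing_fraction": {c: float(f) for c, f in
                                 self.mask.mean().items()},
        }
        (directory / f"{stem}_manifest.json").write_text(
            json.dumps(manifest, indent=2))
        self.mask.astype(int).to_csv(directory / f"{stem}_mask.tsv", sep="\t")


def _bayes_regression_draw(Z: np.ndarray, y: np.ndarray,
                           rng: np.random.Generator,
                           ridge: float = 1e-6
                           ) -> tuple[np.ndarray, np.ndarray]:
    """OLS fit plus a draw from the approximate posterior of (beta, sigma2).

    Returns (beta_hat, beta_draw). Ridge keeps the normal equations solvable
    when predictors are collinear.
    """
    n, p = Z.shape
    ZtZ = Z.T @ Z
    scale = np.trace(ZtZ) / max(p, 1)
    A = ZtZ + ridge * max(scale, 1.0) * np.eye(p)
    Zty = Z.T @ y
    beta_hat = np.linalg.solve(A, Zty)
    resid = y - Z @ beta_hat
    df = max(n - p, 1)
    sse = float(resid @ resid)
    sigma2 = (sse + 1e-12) / stats.chi2.rvs(df, random_state=rng)
    cov = sigma2 * np.linalg.inv(A)
    # symmetrize before Cholesky; tiny jitter guards numerical asymmetry
    cov = (cov + cov.T) / 2 + 1e-12 * np.eye(p)
    L = np.linalg.cholesky(cov)
    beta_draw = beta_hat + L @ rng.standard_normal(p)
    return beta_hat, beta_draw


def _impute_one_copy(X: np.ndarray, miss: np.ndarray, order: Sequence[int],
                     k_donors: int, n_iter: int,
                     rng: np.random.Generator) -> np.ndarray:
    n, p = X.shape
    work = X.copy()
    # initialize from observed marginals
    for j in range(p):
        mj = miss[:, j]
        if mj.any():
            obs = X[~mj, j]
            work[mj, j] = rng.choice(obs, size=int(mj.sum()), replace=True)
    for _ in range(n_iter):
        for j in order:
            mj = miss[:, j]
            if not mj.any():
                continue
            others = [c for c in range(p) if c != j]
            Z = np.column_stack([np.ones(n), work[:, others]])
            y_obs = X[~mj, j]
            beta_hat, beta_draw = _bayes_regression_draw(Z[~mj], y_obs, rng)
            yhat_obs = Z[~mj] @ beta_hat
            yhat_mis = Z[mj] @ beta_draw
            k = min(k_donors, len(y_obs))
            d = np.abs(yhat_obs[None, :] - yhat_mis[:, None])
            donor_pool = np.argpartition(d, k - 1, axis=1)[:, :k]
            pick = donor_pool[np.arange(len(yhat_mis)),
                              rng.integers(k, size=len(yhat_mis))]
            work[mj, j] = y_obs[pick]
    return work


def mice_pmm(matrix: pd.DataFrame,
             config: Optional[ImputationConfig] = None) -> ImputedStack:
    """Chained-equations PMM imputation producing M completed copies.

    Binary 0/1 features are matched on the same linear score, so their
    imputations stay in {0, 1} by the closed-support property. Features are
    visited in order of ascending missingness (ties by column order).
    """
    config = config or ImputationConfig()
    config.validate()
    mask = matrix.isna()
    X = matrix.to_numpy(float)
    miss = mask.to_numpy()
    n, p = X.shape
    n_obs = (~miss).sum(axis=0)
    bad = [matrix.columns[j] for j in range(p) if n_obs[j] < config.k_donors]
    if bad:
        raise ValueError(
            f"features with fewer than k_donors={config.k_donors} observed "
            f"values: {bad}")
    incomplete = [j for j in range(p) if miss[:, j].any()]
    order = sorted(incomplete, key=lambda j: (miss[:, j].sum(), j))

    root = np.random.SeedSequence(config.seed)
    copies = []
    for child in root.spawn(config.m_copies):
        rng = np.random.default_rng(child)
        if not incomplete:
            copies.append(matrix.copy())
            continue
        filled = _impute_one_copy(X, miss, order, config.k_donors,
                                  config.n_chained_iterations, rng)
        copies.append(pd.DataFrame(filled, index=matrix.index,
                                   columns=matrix.columns))
    return ImputedStack(copies, mask, config)


# ---------------------------------------------------------------------------
# Rubin pooling
# ---------------------------------------------------------------------------

@dataclass
class PooledEstimate:
    point: float
    within_var: float
    between_var: float
    total_var: float
    se: float
    ci_low: float
    ci_high: float
    m: int


def rubin_pool(estimates: Sequence[float], variances: Sequence[float],
               ci_level: float = 0.95, use_t: bool = True) -> PooledEstimate:
    """Pool M per-copy estimates: total var = within + (1 + 1/M) * between.

    The CI uses the Barnard-Rubin t reference when ``use_t`` and the
    between-imputation variance is positive, else a normal approximation.
    """
    est = np.asarray(estimates, float)
    var = np.asarray(variances, float)
    if est.shape != var.shape:
        raise ValueError("estimates and variances must have equal length")
    m = len(est)
    if m < 2:
        raise ValueError("need at least 2 imputations to pool")
    point = float(est.mean())
    within = float(var.mean())
    between = float(est.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    se = math.sqrt(total)
    alpha = 1.0 - ci_level
    if se == 0.0:
        crit = 0.0
    elif use_t and between > 0 and within > 0:
        r = (1.0 + 1.0 / m) * between / within
        df = (m - 1) * (1.0 + 1.0 / r) ** 2
        crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    else:
        crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    return PooledEstimate(point, within, between, total, se,
                          point - crit * se, point + crit * se, m)
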