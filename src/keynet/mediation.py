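"""Causal mediation between tissue key drivers and the phenotype.

The three-regression structural model (outcome treated numerically for a
0/1 phenotype, heteroskedasticity-robust standard errors):

    (1)  Y ~ X + covariates          -> c   (total effect)
    (2)  M ~ X + covariates          -> a   (exposure -> mediator)
    (3)  Y ~ M + X + covariates      -> b, c' (mediator effect, direct effect)

Indirect effect = a*b with Sobel normal inference, percentile bootstrap
confidence intervals, and a mediator-permutation test. Screens across all
(exposure, mediator) driver pairs are BH-corrected within each direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats_core import bh_adjust

__all__ = [
    "MediationResult",
    "fit_mediation",
    "bootstrap_indirect",
    "permutation_test",
    "mediation_screen",
]


@dataclass
class MediationResult:
    x_gene: str
    m_gene: str
    outcome: str
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    sobel_se: float
    sobel_p: float
    boot_ci: tuple[float, float] | None = None
    perm_p: float | None = None
    fdr: float = np.nan
    direction: str = ""


def _ols_robust(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and HC1 sandwich standard errors."""
    n, p = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    meat = (X * resid[:, None] ** 2).T @ X
    cov = XtX_inv @ meat @ XtX_inv * (n / max(n - p, 1))
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return beta, se


def _design(covariates: np.ndarray | None, n: int, *cols: np.ndarray) -> np.ndarray:
    parts = [np.ones(n)] + [np.asarray(c, dtype=float) for c in cols]
    if covariates is not None and np.size(covariates):
        parts.append(np.asarray(covariates, dtype=float))
    return np.column_stack(parts)


def _estimate_paths(
    x: np.ndarray, m: np.ndarray, y: np.ndarray, covariates: np.ndarray | None
) -> tuple[float, float, float, float, float, float]:
    """Returns (a, b, c, c_prime, se_a, se_b) from the three regressions."""
    n = x.size
    beta_c, _ = _ols_robust(y, _design(covariates, n, x))
    c = float(beta_c[1])
    beta_a, se_a_vec = _ols_robust(m, _design(covariates, n, x))
    a, se_a = float(beta_a[1]), float(se_a_vec[1])
    beta_b, se_b_vec = _ols_robust(y, _design(covariates, n, m, x))
    b, se_b = float(beta_b[1]), float(se_b_vec[1])
    c_prime = float(beta_b[2])
    return a, b, c, c_prime, se_a, se_b


def fit_mediation(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    x_gene: str = "X",
    m_gene: str = "M",
    outcome: str = "asthma",
) -> MediationResult:
    """Three-regression mediation fit with Sobel inference.

    The linear identity c = c' + a*b holds exactly for nested OLS fits on
    the same sample.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if not (m.size == n and y.size == n):
        raise ValueError("x, m, y must be aligned")
    if n < 30:
        raise ValueError("mediation requires n >= 30")
    if x.std() == 0 or m.std() == 0:
        raise ValueError("constant exposure or mediator")
    a, b, c, c_prime, se_a, se_b = _estimate_paths(x, m, y, covariates)
    indirect = a * b
    sobel_se = float(np.sqrt(b**2 * se_a**2 + a**2 * se_b**2))
    if sobel_se > 0:
        sobel_p = float(2.0 * sps.norm.sf(abs(indirect) / sobel_se))
    else:
        sobel_p = 0.0 if indirect != 0 else 1.0
    return MediationResult(
        x_gene=x_gene,
        m_gene=m_gene,
        outcome=outcome,
        a=a,
        b=b,
        c=c,
        c_prime=c_prime,
        indirect=indirect,
        sobel_se=sobel_se,
        sobel_p=sobel_p,
    )


def bootstrap_indirect(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    B: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile 2.5/97.5 bootstrap CI of the indirect effect a*b.

    Degenerate resamples (constant exposure or mediator) are redrawn, with
    the total number of draws capped at 10*B.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rng = np.random.default_rng(seed)
    stats: list[float] = []
    attempts = 0
    while len(stats) < B and attempts < 10 * B:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        xs, ms = x[idx], m[idx]
        if xs.std() == 0 or ms.std() == 0:
            continue
        cov_s = covariates[idx] if covariates is not None and np.size(covariates) else None
        a, b, *_ = _estimate_paths(xs, ms, y[idx], cov_s)
        stats.append(a * b)
    if not stats:
        raise RuntimeError("all bootstrap resamples were degenerate")
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def permutation_test(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    iterations: int = 10000,
    seed: int = 0,
) -> float:
    """Permute the mediator across samples; p = (1 + #{|ab*| >= |ab|}) / (1 + B)."""
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if iterations <= 0:
        return 1.0
    a, b, *_ = _estimate_paths(x, m, y, covariates)
    observed = abs(a * b)
    rng = np.random.default_rng(seed)
    n = x.size
    exceed = 0
    for _ in range(iterations):
        perm = rng.permutation(n)
        ap, bp, *_ = _estimate_paths(x, m[perm], y, covariates)
        if abs(ap * bp) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + iterations)


def mediation_screen(
    pbmc_drivers: list[str],
    nasal_drivers: list[str],
    pbmc_expr: pd.DataFrame,
    nasal_expr: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
    outcome: str = "asthma",
) -> list[MediationResult]:
    """Test every (PBMC exposure, nasal mediator) pair and the converse.

    Sobel p-values are BH-corrected within each direction; significance is
    FDR <= alpha. Expression frames are genes x samples, aligned with the
    sample table.
    """
    if not pbmc_drivers or not nasal_drivers:
        warnings.warn("empty key driver list; no mediation tests performed")
        return []
    y = samples[outcome].to_numpy(dtype=float)
    results: list[MediationResult] = []
    for direction, (xd, xe, md, me) in {
        "pbmc->nasal": (pbmc_drivers, pbmc_expr, nasal_drivers, nasal_expr),
        "nasal->pbmc": (nasal_drivers, nasal_expr, pbmc_drivers, pbmc_expr),
    }.items():
        batch = []
        for xg in xd:
            for mg in md:
                res = fit_mediation(
                    xe.loc[xg].to_numpy(dtype=float),
                    me.loc[mg].to_numpy(dtype=float),
                    y,
                    covariates=covariates,
                    x_gene=xg,
                    m_gene=mg,
                    outcome=outcome,
                )
                res.direction = direction
                batch.append(res)
        fdr = bh_adjust([r.sobel_p for r in batch])
        for r, q in zip(batch, fdr):
            r.fdr = float(q)
        results.extend(batch)
    return results


def mediation_table(results: list[MediationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "x_gene": r.x_gene,
                "m_gene": r.m_gene,
                "direction": r.direction,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "c_prime": r.c_prime,
                "indirect": r.indirect,
                "sobel_p": r.sobel_p,
                "perm_p": r.perm_p,
                "fdr": r.fdr,
            }
            for r in results
        ],
        columns=[
            "x_gene",
            "m_gene",
            "direction",
            "a",
            "b",
            "c",
            "c_prime",
            "indirect",
            "sobel_p",
            "perm_p",
            "fdr",
        ],
    )
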