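"""Weighted co-expression modules: TOM construction, static-cut module
detection, eigengenes, asthma-gene enrichment and eigengene-phenotype
association.

The network is unsigned (adjacency = |pearson|^beta) and clustered by
average-linkage hierarchical clustering on 1 - TOM with a static height
cut, which keeps the stage fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats as sps

from .stats_core import bh_adjust, hypergeom_enrichment

__all__ = [
    "pick_soft_power",
    "build_tom",
    "detect_modules",
    "compute_eigengene",
    "enrich_modules",
    "associate_eigengenes",
    "ModuleEnrichment",
    "EigengeneAssociation",
]

UNASSIGNED = "unassigned"


@dataclass
class ModuleEnrichment:
    module: str
    overlap: int
    module_size: int
    fold_enrichment: float
    p: float
    fdr: float = np.nan
    is_asthma_module: bool = False


@dataclass
class EigengeneAssociation:
    module: str
    eigengene: np.ndarray
    effect: float
    p: float
    fdr: float = np.nan
    flagged: bool = False  # separation / degenerate fit fallback used


def _abs_corr(expr: np.ndarray) -> np.ndarray:
    sd = expr.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant gene(s): correlations set to 0")
    centered = expr - expr.mean(axis=1, keepdims=True)
    denom = np.where(constant, 1.0, sd * np.sqrt(expr.shape[1]))
    z = centered / denom[:, None]
    corr = np.clip(z @ z.T, -1.0, 1.0)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    return np.abs(corr)


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of log10 p(k) vs log10 mean(k) over equal-width bins."""
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, _, r, *_ = sps.linregress(xs, ys)
    return float(r**2), float(slope)


def pick_soft_power(
    expr: np.ndarray, betas: range = range(1, 21), target_r2: float = 0.8
) -> int:
    """Smallest beta whose degree distribution fits scale-free with
    R^2 >= target (negative slope); falls back to 6."""
    corr = _abs_corr(np.asarray(expr, dtype=float))
    np.fill_diagonal(corr, 0.0)
    for beta in betas:
        k = (corr**beta).sum(axis=1)
        r2, slope = _scale_free_r2(k)
        if r2 >= target_r2 and slope < 0:
            return int(beta)
    return 6


def build_tom(expr: np.ndarray | pd.DataFrame, beta: int | str = 6) -> np.ndarray:
    """Topological overlap matrix of the unsigned weighted network.

    ``expr`` is genes x samples log-scale expression. ``beta`` may be
    "auto" to select the soft power by scale-free fit.
    """
    arr = np.asarray(expr, dtype=float)
    if arr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if beta == "auto":
        beta = pick_soft_power(arr)
    adj = _abs_corr(arr) ** float(beta)
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    shared = adj @ adj
    denom = np.minimum.outer(k, k) + 1.0 - adj
    tom = (shared + adj) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray,
    expr: np.ndarray | pd.DataFrame | None = None,
    gene_ids: list[str] | None = None,
    min_module_size: int = 30,
    merge_corr: float = 0.75,
    cut_height: float = 0.99,
) -> dict[str, str]:
    """Average-linkage clustering on 1 - TOM with a static height cut.

    Clusters smaller than ``min_module_size`` become "unassigned"; modules
    whose eigengenes correlate above ``merge_corr`` are merged (requires
    ``expr``). Labels are mod1, mod2, ... by decreasing size.
    """
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    modules = [idx for idx in clusters.values() if len(idx) >= min_module_size]

    if expr is not None and len(modules) > 1:
        arr = np.asarray(expr, dtype=float)
        merged = True
        while merged and len(modules) > 1:
            eigs = [compute_eigengene(arr[idx]) for idx in modules]
            merged = False
            for i in range(len(modules)):
                for j in range(i + 1, len(modules)):
                    if abs(np.corrcoef(eigs[i], eigs[j])[0, 1]) > merge_corr:
                        modules[i] = sorted(modules[i] + modules[j])
                        del modules[j]
                        merged = True
                        break
                if merged:
                    break

    modules.sort(key=lambda idx: (-len(idx), idx[0]))
    assignment = {g: UNASSIGNED for g in gene_ids}
    for m, idx in enumerate(modules, start=1):
        for i in idx:
            assignment[gene_ids[i]] = f"mod{m}"
    return assignment


def compute_eigengene(expr_sub: np.ndarray | pd.DataFrame) -> np.ndarray:
    """First right singular vector of the gene-standardized module matrix,
    unit norm, sign-oriented so its correlation with the module-average
    expression is non-negative."""
    arr = np.asarray(expr_sub, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("module must contain at least 2 genes")
    sd = arr.std(axis=1)
    if (sd == 0).all():
        raise ValueError("zero-variance module")
    sd = np.where(sd == 0, 1.0, sd)
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    avg = z.mean(axis=0)
    if np.dot(eig, avg) < 0:
        eig = -eig
    return eig / np.linalg.norm(eig)


def enrich_modules(
    assignment: dict[str, str],
    asthma_genes: set[str] | list[str],
    universe: set[str] | list[str],
    alpha: float = 0.05,
) -> list[ModuleEnrichment]:
    """Hypergeometric enrichment of each module for the asthma gene set;
    flagged as an asthma module iff fold > 1 and BH FDR <= alpha."""
    universe = set(universe)
    asthma = set(asthma_genes)
    if not asthma <= universe:
        raise ValueError("asthma genes must be a subset of the universe")
    modules: dict[str, set[str]] = {}
    for g, lab in assignment.items():
        if lab != UNASSIGNED and g in universe:
            modules.setdefault(lab, set()).add(g)
    results = []
    for lab in sorted(modules):
        members = modules[lab]
        overlap = len(members & asthma)
        fold, p = hypergeom_enrichment(overlap, len(members), len(asthma), len(universe))
        results.append(
            ModuleEnrichment(
                module=lab,
                overlap=overlap,
                module_size=len(members),
                fold_enrichment=fold,
                p=p,
            )
        )
    if results:
        fdr = bh_adjust([r.p for r in results])
        for r, q in zip(results, fdr):
            r.fdr = float(q)
            r.is_asthma_module = bool(r.fold_enrichment > 1 and r.fdr <= alpha)
        results.sort(key=lambda r: (-r.fold_enrichment, r.fdr))
    return results


def _logistic_score_test(x: np.ndarray, y: np.ndarray, covariates: np.ndarray) -> float:
    """Score test for adding x to a null logistic model with covariates."""
    import statsmodels.api as sm

    null = sm.Logit(y, covariates).fit(disp=0, maxiter=200)
    p0 = null.predict(covariates)
    w = p0 * (1 - p0)
    # residualize x against covariates under the null information metric
    WX = covariates * w[:, None]
    coef, *_ = np.linalg.lstsq(WX.T @ covariates, WX.T @ x, rcond=None)
    r = x - covariates @ coef
    u = float(r @ (y - p0))
    v = float((r**2 * w).sum())
    if v <= 0:
        return 1.0
    return float(sps.chi2.sf(u**2 / v, df=1))


def associate_eigengenes(
    eigengenes: dict[str, np.ndarray],
    samples: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "race"),
    condition: str = "asthma",
) -> list[EigengeneAssociation]:
    """Logistic regression of phenotype on each module eigengene plus
    covariates; BH across modules; ranked by |effect| then FDR.

    Degenerate fits (separation, non-convergence, constant eigengene)
    fall back to a score test computed under the covariate-only null and
    are flagged.
    """
    import statsmodels.api as sm

    from .diffexpr import build_design

    X_cov, names = build_design(samples, covariates=covariates, condition=condition)
    cov_only = np.delete(X_cov, names.index(condition), axis=1)
    y = samples[condition].to_numpy(dtype=float)
    results = []
    for lab in sorted(eigengenes):
        eig = np.asarray(eigengenes[lab], dtype=float)
        if eig.std() == 0:
            results.append(
                EigengeneAssociation(module=lab, eigengene=eig, effect=0.0, p=1.0, flagged=True)
            )
            continue
        design = np.column_stack([cov_only, eig])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            effect = float(fit.params[-1])
            p = float(fit.pvalues[-1])
            flagged = not bool(fit.mle_retvals.get("converged", True)) or not np.isfinite(p)
        except Exception:
            effect, p, flagged = np.nan, np.nan, True
        if flagged or not np.isfinite(p):
            p = _logistic_score_test(eig, y, cov_only)
            if not np.isfinite(effect):
                effect = 0.0
            flagged = True
        results.append(
            EigengeneAssociation(module=lab, eigengene=eig, effect=effect, p=p, flagged=flagged)
        )
    if results:
        fdr = bh_adjust([r.p for r in results])
        for r, q in zip(results, fdr):
            r.fdr = float(q)
        results.sort(key=lambda r: (-abs(r.effect), r.fdr))
    return results
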