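"""cis-eQTL mapping: MAF filtering, genotype PCs, and per-pair linear models.

Each (gene, SNP) pair with the SNP inside the closed window
[TSS - window, TES + window] is tested by OLS of log-CPM expression on
dosage plus covariates (t-test on the slope), with BH correction across
all tested pairs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenotypeTable
from .stats_core import bh_adjust

__all__ = ["filter_variants", "genotype_pcs", "map_cis_eqtl", "eqtl_anchored_genes"]


def filter_variants(genotypes: GenotypeTable, min_maf: float = 0.01) -> GenotypeTable:
    """Retain variants with sample minor-allele frequency >= ``min_maf``."""
    f = genotypes.dosages.mean(axis=1) / 2.0
    maf = np.minimum(f, 1.0 - f)
    return genotypes.subset(maf >= min_maf - 1e-12)


def genotype_pcs(genotypes: GenotypeTable, k: int) -> np.ndarray:
    """Top-k PCs (samples x k) of the centered, variance-scaled dosages.

    Deterministic up to sign; each component's sign is fixed so its
    largest-magnitude SNP loading is positive.
    """
    n = genotypes.dosages.shape[1]
    if k >= n:
        raise ValueError(f"k ({k}) must be smaller than the sample count ({n})")
    G = genotypes.dosages.astype(float).T  # samples x snps
    G = G - G.mean(axis=0)
    sd = G.std(axis=0)
    sd[sd == 0] = 1.0
    G = G / sd
    u, s, vt = np.linalg.svd(G, full_matrices=False)
    pcs = u[:, :k] * s[:k]
    for j in range(min(k, vt.shape[0])):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


def _residualize(M: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Residuals of the columns of M against the column space of Q."""
    coef, *_ = np.linalg.lstsq(Q, M, rcond=None)
    return M - Q @ coef


def map_cis_eqtl(
    expr: pd.DataFrame,
    genotypes: GenotypeTable,
    annotation: pd.DataFrame,
    covariates: np.ndarray | None = None,
    window: int = 1_000_000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every cis (gene, SNP) pair; returns a frame with
    ``gene, snp, beta, t, p, fdr, significant``.

    ``expr`` is genes x samples log-CPM aligned with the genotype samples;
    ``covariates`` is an optional samples x q matrix (no intercept needed).
    """
    n = expr.shape[1]
    if genotypes.dosages.shape[1] != n:
        raise ValueError("expression and genotype sample counts differ")
    ann = annotation.set_index("gene_id")
    Q = np.ones((n, 1))
    if covariates is not None and covariates.size:
        Q = np.column_stack([Q, np.asarray(covariates, dtype=float)])
    q = np.linalg.matrix_rank(Q)
    dof = n - q - 1
    if dof <= 0:
        raise ValueError("not enough samples for covariate-adjusted eQTL test")

    E = _residualize(np.asarray(expr, dtype=float).T, Q)  # samples x genes
    D = _residualize(genotypes.dosages.astype(float).T, Q)  # samples x snps

    snp_pos = genotypes.pos
    snp_chrom = np.asarray(genotypes.chrom)
    records = []
    for gi, gene in enumerate(expr.index):
        if gene not in ann.index:
            warnings.warn(f"gene {gene} missing from annotation; skipped")
            continue
        row = ann.loc[gene]
        in_window = (
            (snp_chrom == str(row["chrom"]))
            & (snp_pos >= int(row["tss"]) - window)
            & (snp_pos <= int(row["tes"]) + window)
        )
        for si in np.flatnonzero(in_window):
            g = D[:, si]
            e = E[:, gi]
            gg = float(g @ g)
            if gg <= 1e-12:
                continue  # dosage fully explained by covariates
            beta = float(g @ e) / gg
            resid = e - beta * g
            sigma2 = float(resid @ resid) / dof
            se = np.sqrt(sigma2 / gg)
            if se == 0:
                t = np.inf if beta != 0 else 0.0
                p = 0.0 if beta != 0 else 1.0
            else:
                t = beta / se
                p = float(2.0 * sps.t.sf(abs(t), dof))
            records.append((gene, genotypes.snp_ids[si], beta, float(t), p))
    df = pd.DataFrame(records, columns=["gene", "snp", "beta", "t", "p"])
    if len(df):
        df["fdr"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["fdr"] <= alpha
    else:
        df["fdr"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


def eqtl_anchored_genes(eqtl_results: pd.DataFrame) -> set[str]:
    """Genes with at least one significant cis-eQTL (network prior anchors)."""
    if len(eqtl_results) == 0:
        return set()
    return set(eqtl_results.loc[eqtl_results["significant"], "gene"])
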