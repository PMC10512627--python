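"""Two-tissue synthetic cohort generator with machine-readable ground truth.

A cohort consists of negative-binomial count matrices for two tissues
("pbmc" and "nasal") over a shared sample set, a phenotype/covariate table,
biallelic genotype dosages, gene annotation, and a :class:`TruthSet`
recording every planted signal:

* per-tissue co-expression modules generated from a directed causal graph
  whose roots are designated key drivers,
* cis-eQTL genotype effects on key-driver expression,
* case/control differential expression planted on module members,
* a cross-tissue mediation chain: a PBMC key driver X drives a nasal key
  driver M (M = a*X + noise), and a liability L = b*M + c'*X + noise is
  thresholded to the binary phenotype at the configured case fraction.

Latent expression lives on the natural-log scale; counts are drawn from a
gamma-Poisson mixture with a gene-shared dispersion, scaled by log-normal
per-sample size factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    GenotypeTable,
    read_annotation,
    read_counts,
    read_json,
    read_samples,
    read_vcf,
    write_annotation,
    write_counts,
    write_json,
    write_samples,
    write_vcf,
)

__all__ = ["SimConfig", "TruthSet", "Cohort", "generate_cohort", "write_cohort", "read_cohort"]

TISSUES = ("pbmc", "nasal")
GENE_PREFIX = {"pbmc": "PB", "nasal": "NS"}
TISSUE_CHROM = {"pbmc": "1", "nasal": "2"}
GENE_SPACING = 3_000_000  # keeps cis windows of adjacent genes disjoint


@dataclass
class SimConfig:
    """Parameters of a synthetic cohort; defaults give desk-scale power."""

    n_samples: int = 300
    case_fraction: float = 0.5
    n_genes_per_tissue: int = 1000
    n_modules: int = 3
    module_size: int = 50
    n_key_drivers_per_module: int = 3
    n_snps: int = 40
    maf_range: tuple[float, float] = (0.2, 0.5)
    eqtl_effect: float = 0.8
    de_log_fold_change: float = 1.0
    mediation_a: float = 0.5
    mediation_b: float = 0.5
    direct_c: float = 0.0  # non-zero X->phenotype path makes the converse
    # mediation partially true, so the default plants a pure indirect chain
    nb_dispersion: float = 0.1
    edge_weight: float = 0.7
    seed: int = 0
    # internal knobs (not part of the planted-signal surface)
    latent_sd: float = 0.4
    liability_sd: float = 0.5
    base_log_mean: tuple[float, float] = (4.0, 6.0)
    size_factor_sd: float = 0.2

    def validate(self) -> None:
        if self.n_samples < 20:
            raise ValueError("n_samples must be >= 20")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie strictly between 0 and 1")
        if self.module_size < self.n_key_drivers_per_module + 2:
            raise ValueError("module_size must be >= n_key_drivers_per_module + 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_modules * self.module_size > self.n_genes_per_tissue:
            raise ValueError(
                "module genes exceed gene count: "
                f"{self.n_modules} x {self.module_size} > {self.n_genes_per_tissue}"
            )
        n_eqtl = 2 * self.n_modules * self.n_key_drivers_per_module
        if self.n_snps < n_eqtl:
            raise ValueError(
                f"n_snps ({self.n_snps}) must cover one cis SNP per key driver ({n_eqtl})"
            )


@dataclass
class TruthSet:
    """All planted parameters of a synthetic cohort."""

    de_genes: dict[str, dict[str, float]]  # tissue -> gene -> signed natural-log FC
    module_membership: dict[str, dict[str, str]]  # tissue -> gene -> module label
    causal_edges: dict[str, list[tuple[str, str]]]  # tissue -> directed gene pairs
    key_drivers: dict[str, list[str]]  # "tissue/module" -> gene list
    eqtl_pairs: list[tuple[str, str, float]]  # (snp, gene, effect)
    mediation: dict  # x_gene, m_gene, a, b, c_prime

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, obj: dict) -> "TruthSet":
        return cls(
            de_genes=obj["de_genes"],
            module_membership=obj["module_membership"],
            causal_edges={
                t: [tuple(e) for e in edges] for t, edges in obj["causal_edges"].items()
            },
            key_drivers=obj["key_drivers"],
            eqtl_pairs=[tuple(e) for e in obj["eqtl_pairs"]],
            mediation=obj["mediation"],
        )


@dataclass
class Cohort:
    counts: dict[str, CountMatrix]  # tissue -> matrix
    samples: pd.DataFrame
    genotypes: GenotypeTable
    annotation: pd.DataFrame
    truth: TruthSet
    config: SimConfig | None = None


def _gene_ids(tissue: str, n: int) -> list[str]:
    return [f"{GENE_PREFIX[tissue]}{i:05d}" for i in range(n)]


def _plant_module_dag(
    genes: list[str], n_drivers: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Directed acyclic graph over a module: the designated drivers form a
    chain at the top (so the module shares ancestry and is cohesive), and
    every later gene gets one driver parent plus optionally one earlier
    non-driver parent."""
    edges: list[tuple[str, str]] = []
    for j in range(1, n_drivers):
        edges.append((genes[j - 1], genes[j]))
    for j in range(n_drivers, len(genes)):
        driver = genes[int(rng.integers(0, n_drivers))]
        edges.append((driver, genes[j]))
        if j > n_drivers and rng.random() < 0.5:
            other = genes[int(rng.integers(n_drivers, j))]
            if other != genes[j]:
                edges.append((other, genes[j]))
    return sorted(set(edges))


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate a deterministic two-tissue cohort from ``config``.

    Same seed => byte-identical outputs when written with
    :func:`write_cohort`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # --- genotypes -------------------------------------------------------
    n_snps = config.n_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_snps)
    u = rng.random((n_snps, n, 2))
    dosages = (u < mafs[:, None, None]).sum(axis=2).astype(np.int8)  # HWE

    # --- gene layout, modules, causal DAGs -------------------------------
    gene_ids = {t: _gene_ids(t, config.n_genes_per_tissue) for t in TISSUES}
    module_membership: dict[str, dict[str, str]] = {t: {} for t in TISSUES}
    causal_edges: dict[str, list[tuple[str, str]]] = {t: [] for t in TISSUES}
    key_drivers: dict[str, list[str]] = {}
    polarity: dict[str, float] = {}
    eqtl_pairs: list[tuple[str, str, float]] = []
    snp_gene: list[str | None] = [None] * n_snps  # cis gene per SNP (if any)
    snp_cursor = 0

    edge_coef: dict[tuple[str, str], float] = {}
    for t in TISSUES:
        offset = 0
        all_drivers: set[str] = set()
        for m in range(config.n_modules):
            members = gene_ids[t][offset : offset + config.module_size]
            offset += config.module_size
            label = f"mod{m}"
            for g in members:
                module_membership[t][g] = label
            drivers = members[: config.n_key_drivers_per_module]
            all_drivers.update(drivers)
            key_drivers[f"{t}/{label}"] = list(drivers)
            # alternate regulation polarity among non-driver members; edge
            # coefficients and planted DE signs both follow polarity so the
            # module's correlation structure stays coherent
            for j, g in enumerate(members):
                polarity[g] = 1.0 if (j < len(drivers) or (j - len(drivers)) % 2 == 0) else -1.0
            if config.edge_weight != 0.0:
                for e in _plant_module_dag(members, len(drivers), rng):
                    causal_edges[t].append(e)
                    edge_coef[e] = config.edge_weight * polarity[e[0]] * polarity[e[1]]
            for d in drivers:
                eqtl_pairs.append((f"rs{snp_cursor:05d}", d, config.eqtl_effect))
                snp_gene[snp_cursor] = d
                snp_cursor += 1
        # sparse background web plus weak background -> member inputs: gives
        # key driver analysis a connected non-member neighborhood that is
        # *not* downstream of the planted driver roots
        background = gene_ids[t][offset:]
        for g in background:
            polarity[g] = 1.0
        if config.edge_weight != 0.0:
            for j in range(1, len(background)):
                if rng.random() < 0.4:
                    p = background[int(rng.integers(0, j))]
                    e = (p, background[j])
                    causal_edges[t].append(e)
                    edge_coef[e] = config.edge_weight
            if background:
                for g, lab in module_membership[t].items():
                    if g in all_drivers:
                        continue
                    if rng.random() < 0.5:
                        p = background[int(rng.integers(0, len(background)))]
                        e = (p, g)
                        if e not in edge_coef:
                            causal_edges[t].append(e)
                            edge_coef[e] = config.edge_weight * polarity[g]

    # --- annotation and SNP coordinates ----------------------------------
    ann_rows = []
    tss_of: dict[str, tuple[str, int]] = {}
    for t in TISSUES:
        for i, g in enumerate(gene_ids[t]):
            tss = 1 + i * GENE_SPACING
            ann_rows.append((g, TISSUE_CHROM[t], tss, tss + 1000))
            tss_of[g] = (TISSUE_CHROM[t], tss)
    annotation = pd.DataFrame(ann_rows, columns=["gene_id", "chrom", "tss", "tes"])

    snp_ids = [f"rs{i:05d}" for i in range(n_snps)]
    snp_chrom: list[str] = []
    snp_pos = np.empty(n_snps, dtype=np.int64)
    background_cursor = 0
    for i in range(n_snps):
        g = snp_gene[i]
        if g is not None:
            chrom, tss = tss_of[g]
            snp_chrom.append(chrom)
            snp_pos[i] = tss + 500
        else:
            # park background SNPs on their own contig, away from any gene
            snp_chrom.append("9")
            snp_pos[i] = 1 + background_cursor * 10_000
            background_cursor += 1
    genotypes = GenotypeTable(
        snp_ids=snp_ids, chrom=snp_chrom, pos=snp_pos, dosages=dosages, sample_ids=sample_ids
    )
    dosage_of = {g: dosages[i].astype(float) for i, g in enumerate(snp_gene) if g is not None}

    # --- latent log-expression by topological propagation ----------------
    # the mediation chain is planted as a cross-tissue edge X -> M so a
    # single propagation pass covers it (PBMC latents resolve before nasal)
    x_gene = key_drivers["pbmc/mod0"][0]
    m_gene = key_drivers["nasal/mod0"][0]
    parents: dict[str, list[str]] = {}
    for t in TISSUES:
        for u_, v_ in causal_edges[t]:
            parents.setdefault(v_, []).append(u_)
    parents.setdefault(m_gene, []).append(x_gene)
    edge_coef[(x_gene, m_gene)] = config.mediation_a

    # per-gene noise drawn in a fixed order so the RNG stream (and thus all
    # other genes) is unchanged by the planted graph structure
    noise: dict[str, np.ndarray] = {}
    for t in TISSUES:
        for g in gene_ids[t]:
            # background genes get a wider latent spread so the planted
            # background->member inputs are strong enough to be learnable
            sd = config.latent_sd if g in module_membership[t] else 1.6 * config.latent_sd
            noise[g] = rng.normal(0.0, sd, size=n)

    latent: dict[str, np.ndarray] = {}

    def _resolve(g: str) -> np.ndarray:
        if g in latent:
            return latent[g]
        vals = noise[g].copy()
        for p in parents.get(g, ()):
            vals += edge_coef[(p, g)] * _resolve(p)
        if g in dosage_of:
            vals += config.eqtl_effect * dosage_of[g]
        latent[g] = vals
        return vals

    for t in TISSUES:
        for g in gene_ids[t]:
            _resolve(g)

    liability = (
        config.mediation_b * latent[m_gene]
        + config.direct_c * latent[x_gene]
        + rng.normal(0.0, config.liability_sd, size=n)
    )
    n_cases = int(round(n * config.case_fraction))
    n_cases = min(max(n_cases, 1), n - 1)
    order = np.argsort(liability, kind="mergesort")
    asthma = np.zeros(n, dtype=np.int64)
    asthma[order[n - n_cases :]] = 1

    # --- planted differential expression ---------------------------------
    de_genes: dict[str, dict[str, float]] = {t: {} for t in TISSUES}
    chain = {x_gene, m_gene}
    if config.de_log_fold_change != 0.0:
        for t in TISSUES:
            mod0 = [g for g, lab in module_membership[t].items() if lab == "mod0"]
            # symmetric +/- lfc/2 shifts keep the expected transcript mass of
            # the DE set equal between groups (plain CPM stays unbiased for
            # non-DE genes); the sign follows each gene's regulation
            # polarity so DE reinforces rather than fights module structure
            for g in mod0:
                if g in chain:
                    continue
                lfc = config.de_log_fold_change * polarity[g]
                latent[g] = latent[g] + lfc * (asthma - 0.5)
                de_genes[t][g] = float(lfc)

    # --- covariates ------------------------------------------------------
    age = np.round(rng.uniform(6, 21, size=n), 1)
    sex = rng.choice(["F", "M"], size=n)
    race = rng.choice(["A", "B", "C"], size=n, p=[0.5, 0.3, 0.2])
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "asthma": asthma,
            "age": age,
            "sex": sex,
            "race": race,
        }
    )

    # --- negative-binomial counts ----------------------------------------
    counts: dict[str, CountMatrix] = {}
    for t in TISSUES:
        base = rng.uniform(*config.base_log_mean, size=config.n_genes_per_tissue)
        # module genes get low-mass baselines so their (correlated) latent
        # fluctuations contribute negligibly to the library total; otherwise
        # the composition share of every background gene inherits a common
        # anti-correlated factor
        lo, hi = config.base_log_mean
        in_module = np.array([g in module_membership[t] for g in gene_ids[t]])
        base[in_module] = lo + (base[in_module] - lo) * 0.35
        size_factors = np.exp(rng.normal(0.0, config.size_factor_sd, size=n))
        lat = np.vstack([latent[g] for g in gene_ids[t]])
        mu = np.exp(base[:, None] + lat)
        # pin each sample's expected library mass to its size factor: the
        # per-sample rescale is transparent to CPM-based inference but stops
        # module-mass fluctuations from leaking a shared factor (and a
        # case/control composition bias) into every other gene's CPM
        mu = mu / mu.sum(axis=0)[None, :] * np.exp(base).sum() * size_factors[None, :]
        disp = config.nb_dispersion
        if disp < 1e-12:
            mat = rng.poisson(mu)
        else:
            lam = rng.gamma(shape=1.0 / disp, scale=mu * disp)
            mat = rng.poisson(lam)
        df = pd.DataFrame(mat.astype(np.int64), index=gene_ids[t], columns=sample_ids)
        df.index.name = "gene_id"
        counts[t] = CountMatrix(counts=df, tissue=t)

    truth = TruthSet(
        de_genes=de_genes,
        module_membership=module_membership,
        causal_edges=causal_edges,
        key_drivers=key_drivers,
        eqtl_pairs=eqtl_pairs,
        mediation={
            "x_gene": x_gene,
            "m_gene": m_gene,
            "a": config.mediation_a,
            "b": config.mediation_b,
            "c_prime": config.direct_c,
        },
    )
    return Cohort(
        counts=counts,
        samples=samples,
        genotypes=genotypes,
        annotation=annotation,
        truth=truth,
        config=config,
    )


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort as plain-text files; round-trips through read_cohort."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for t, cm in cohort.counts.items():
        p = directory / f"counts_{t}.tsv"
        write_counts(cm, p)
        paths[f"counts_{t}"] = p
    paths["samples"] = directory / "samples.tsv"
    write_samples(cohort.samples, paths["samples"])
    paths["genotypes"] = directory / "genotypes.vcf"
    write_vcf(cohort.genotypes, paths["genotypes"])
    paths["annotation"] = directory / "annotation.tsv"
    write_annotation(cohort.annotation, paths["annotation"])
    paths["truth"] = directory / "truth.json"
    write_json(cohort.truth.to_json(), paths["truth"])
    return paths


def read_cohort(directory: str | Path) -> Cohort:
    directory = Path(directory)
    counts = {
        t: read_counts(directory / f"counts_{t}.tsv", tissue=t)
        for t in TISSUES
        if (directory / f"counts_{t}.tsv").exists()
    }
    return Cohort(
        counts=counts,
        samples=read_samples(directory / "samples.tsv"),
        genotypes=read_vcf(directory / "genotypes.vcf"),
        annotation=read_annotation(directory / "annotation.tsv"),
        truth=TruthSet.from_json(read_json(directory / "truth.json")),
    )
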