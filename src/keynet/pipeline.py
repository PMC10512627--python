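"""End-to-end orchestration of the per-tissue and cross-tissue analyses.

Stage order per tissue: CPM normalization and abundance filtering ->
discovery/test split -> differential expression with directional
validation -> co-expression modules (enrichment + eigengene association)
-> cis-eQTL mapping -> causal network reconstruction (discovery and test
separately) -> key driver analysis with validation. Integration runs the
mediation screen between validated key drivers of the two tissues.

A single configured seed deterministically derives per-stage seeds (SHA-256
of stage name + seed), so every stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression, diffexpr, eqtl, keydriver, mediation, preprocess
from .causalnet import EqtlPrior, consensus, discretize, mcmc_sample
from .io import CountMatrix, read_annotation, read_counts, read_samples, read_vcf
from .keydriver import key_driver_table
from .mediation import mediation_table

logger = logging.getLogger("keynet.pipeline")

__all__ = ["PipelineConfig", "run_tissue", "run_integration", "run_all", "stage_seed"]


@dataclass
class PipelineConfig:
    """Paths and stage parameters; defaults are the published thresholds."""

    counts: dict[str, str] = field(default_factory=dict)  # tissue -> TSV path
    samples: str = ""
    genotypes: str = ""
    annotation: str = ""
    out_dir: str = "pipeline_out"
    tissues: tuple[str, ...] = ("pbmc", "nasal")
    seed: int = 0
    # preprocess
    cpm_threshold: float = 5.0
    max_low_fraction: float = 0.10
    stratify_split: bool = False
    # differential expression
    covariates: tuple[str, ...] = ("age", "sex", "race")
    dge_alpha: float = 0.05
    strict_validation: bool = False
    # co-expression
    beta: int | str = 6
    min_module_size: int = 30
    merge_corr: float = 0.75
    enrich_alpha: float = 0.05
    # eQTL
    min_maf: float = 0.01
    eqtl_window: int = 1_000_000
    n_genotype_pcs: int = 3
    eqtl_alpha: float = 0.05
    # causal network
    n_networks: int = 25
    sweeps_per_gene: int = 60
    max_parents: int = 3
    consensus_threshold: float = 0.30
    kappa: float = 1.0
    lam: float = float(np.log(2.0))
    max_network_genes: int = 120
    # key drivers
    kda_K: int = 7
    min_downstream: int = 5
    kda_alpha: float = 0.05
    # mediation
    mediation_iterations: int = 10000
    mediation_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for tissue, p in cfg.counts.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"counts file for {tissue} not found: {p}")
        for name in ("samples", "genotypes", "annotation"):
            p = getattr(cfg, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        return cfg


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the pipeline seed."""
    digest = hashlib.sha256(f"{stage}:{base_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class TissueResult:
    tissue: str
    kept_genes: list[str]
    split: preprocess.SplitAssignment
    dge_discovery: pd.DataFrame
    dge_test: pd.DataFrame
    asthma_genes: diffexpr.ValidatedGeneSet
    modules: dict[str, str]
    enrichment: list
    eigengene_assoc: list
    eqtls: pd.DataFrame
    network_discovery: object
    network_test: object
    key_drivers: dict[str, list]
    validated_drivers: list[str]
    log_cpm: pd.DataFrame


def run_tissue(
    config: PipelineConfig,
    tissue: str,
    counts: CountMatrix | None = None,
    samples: pd.DataFrame | None = None,
    genotypes=None,
    annotation: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> TissueResult:
    """Run the full per-tissue pipeline and write its artifact files."""
    try:
        return _run_tissue(config, tissue, counts, samples, genotypes, annotation, out_dir)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed for tissue {tissue!r}: {exc}") from exc


def _run_tissue(config, tissue, counts, samples, genotypes, annotation, out_dir) -> TissueResult:
    if counts is None:
        counts = read_counts(config.counts[tissue], tissue=tissue)
    if samples is None:
        samples = read_samples(config.samples)
    if genotypes is None:
        genotypes = read_vcf(config.genotypes)
    if annotation is None:
        annotation = read_annotation(config.annotation)
    out = Path(out_dir if out_dir is not None else Path(config.out_dir) / tissue)
    out.mkdir(parents=True, exist_ok=True)
    samples = samples.set_index("sample_id").loc[counts.sample_ids].reset_index()

    # --- preprocess ------------------------------------------------------
    cpm = preprocess.cpm_normalize(counts)
    kept = preprocess.filter_low_abundance(
        cpm, threshold=config.cpm_threshold, max_low_fraction=config.max_low_fraction
    )
    logger.info("%s: %d/%d genes pass abundance filter", tissue, len(kept), cpm.shape[0])
    filtered = CountMatrix(counts.counts.loc[kept], tissue=tissue)
    logcpm = np.log(cpm.loc[kept] + 1.0)

    split = preprocess.split_discovery_test(
        samples, seed=stage_seed(config.seed, "split"), stratify=config.stratify_split
    )
    disc_ids, test_ids = list(split.discovery), list(split.test)

    def subset(cm: CountMatrix, ids: list[str]) -> CountMatrix:
        return CountMatrix(cm.counts[ids], tissue=cm.tissue)

    disc_samples = samples[samples["sample_id"].isin(disc_ids)]
    test_samples = samples[samples["sample_id"].isin(test_ids)]

    # --- differential expression ----------------------------------------
    dge_disc = diffexpr.fit_nb_glm(
        subset(filtered, disc_ids), disc_samples, covariates=config.covariates
    )
    dge_test = diffexpr.fit_nb_glm(
        subset(filtered, test_ids), test_samples, covariates=config.covariates
    )
    asthma_genes = diffexpr.validate_across_sets(
        dge_disc, dge_test, alpha=config.dge_alpha, strict=config.strict_validation
    )
    logger.info("%s: %d validated asthma genes", tissue, len(asthma_genes.genes))

    # --- co-expression modules (discovery set) ---------------------------
    disc_expr = logcpm[disc_ids]
    tom = coexpression.build_tom(disc_expr, beta=config.beta)
    modules = coexpression.detect_modules(
        tom,
        expr=disc_expr,
        gene_ids=kept,
        min_module_size=config.min_module_size,
        merge_corr=config.merge_corr,
    )
    enrichment = coexpression.enrich_modules(
        modules, asthma_genes.genes, kept, alpha=config.enrich_alpha
    )
    eigengenes = {}
    for lab in sorted({m for m in modules.values() if m != coexpression.UNASSIGNED}):
        idx = [g for g, l in modules.items() if l == lab]
        eigengenes[lab] = coexpression.compute_eigengene(disc_expr.loc[idx])
    eigengene_assoc = (
        coexpression.associate_eigengenes(eigengenes, disc_samples, covariates=config.covariates)
        if eigengenes
        else []
    )

    # --- cis-eQTL mapping -------------------------------------------------
    gt = eqtl.filter_variants(genotypes, min_maf=config.min_maf)
    pcs = eqtl.genotype_pcs(gt, k=config.n_genotype_pcs)
    age = samples["age"].to_numpy(dtype=float)
    sex = (samples["sex"].astype(str) == "M").to_numpy(dtype=float)
    covs = np.column_stack([age, sex, pcs])
    eqtls = eqtl.map_cis_eqtl(
        logcpm,
        gt,
        annotation,
        covariates=covs,
        window=config.eqtl_window,
        alpha=config.eqtl_alpha,
    )
    anchored = eqtl.eqtl_anchored_genes(eqtls)

    # --- causal network (discovery and test separately) ------------------
    asthma_modules = [e.module for e in enrichment if e.is_asthma_module]
    if not asthma_modules and enrichment:
        asthma_modules = [enrichment[0].module]
    network_genes: list[str] = []
    for lab in asthma_modules:
        network_genes.extend(g for g, l in modules.items() if l == lab)
    network_genes = sorted(set(network_genes))[: config.max_network_genes]
    # pad with the non-module genes most correlated with the module so the
    # key-driver background is not the module itself
    n_pad = config.max_network_genes - len(network_genes)
    if n_pad > 0 and network_genes:
        pool = [g for g in kept if modules.get(g) == coexpression.UNASSIGNED]
        if pool:
            mod_expr = logcpm.loc[network_genes].to_numpy()
            pool_expr = logcpm.loc[pool].to_numpy()
            mz = (mod_expr - mod_expr.mean(1, keepdims=True)) / (
                mod_expr.std(1, keepdims=True) + 1e-12
            )
            pz = (pool_expr - pool_expr.mean(1, keepdims=True)) / (
                pool_expr.std(1, keepdims=True) + 1e-12
            )
            best = np.abs(pz @ mz.T / mod_expr.shape[1]).max(axis=1)
            order = np.argsort(-best, kind="mergesort")[:n_pad]
            network_genes = sorted(set(network_genes) | {pool[i] for i in order})
    prior = EqtlPrior(anchored=anchored, kappa=config.kappa, lam=config.lam)

    def build_network(ids: list[str], tag: str):
        if len(network_genes) < 2:
            return None
        data = discretize(
            logcpm.loc[network_genes, ids],
            seed=stage_seed(config.seed, f"discretize-{tissue}-{tag}"),
        )
        nets = mcmc_sample(
            data,
            prior=prior,
            n_networks=config.n_networks,
            sweeps=config.sweeps_per_gene * len(network_genes),
            max_parents=config.max_parents,
            seed=stage_seed(config.seed, f"mcmc-{tissue}-{tag}"),
        )
        return consensus(nets, threshold=config.consensus_threshold)

    net_disc = build_network(disc_ids, "discovery")
    net_test = build_network(test_ids, "test")

    # --- key driver analysis ---------------------------------------------
    key_drivers: dict[str, list] = {}
    validated: list[str] = []
    if net_disc is not None and net_test is not None:
        for lab in asthma_modules:
            members = {g for g, l in modules.items() if l == lab and g in network_genes}
            if not members:
                continue
            kd_disc = keydriver.find_key_drivers(
                net_disc,
                members,
                K=config.kda_K,
                min_downstream=config.min_downstream,
                alpha=config.kda_alpha,
            )
            kd_test = keydriver.find_key_drivers(
                net_test,
                members,
                K=config.kda_K,
                min_downstream=config.min_downstream,
                alpha=config.kda_alpha,
            )
            merged = keydriver.validate_key_drivers(kd_disc, kd_test)
            key_drivers[lab] = merged
            validated.extend(r.node for r in merged if r.validated)

    # --- artifacts --------------------------------------------------------
    _fmt(dge_disc.reset_index(drop=True), out / "dge_discovery.tsv")
    _fmt(dge_test.reset_index(drop=True), out / "dge_test.tsv")
    _fmt(
        pd.DataFrame(
            {
                "gene": asthma_genes.genes,
                "direction": [asthma_genes.direction[g] for g in asthma_genes.genes],
            }
        ),
        out / "asthma_genes.tsv",
    )
    _fmt(
        pd.DataFrame({"gene": list(modules), "module": [modules[g] for g in modules]}),
        out / "modules.tsv",
    )
    _fmt(
        pd.DataFrame(
            [
                {
                    "module": e.module,
                    "overlap": e.overlap,
                    "module_size": e.module_size,
                    "fold_enrichment": e.fold_enrichment,
                    "p": e.p,
                    "fdr": e.fdr,
                    "is_asthma_module": e.is_asthma_module,
                }
                for e in enrichment
            ],
            columns=[
                "module",
                "overlap",
                "module_size",
                "fold_enrichment",
                "p",
                "fdr",
                "is_asthma_module",
            ],
        ),
        out / "enrichment.tsv",
    )
    _fmt(eqtls, out / "eqtls.tsv")
    net_frames = []
    for tag, net in (("discovery", net_disc), ("test", net_test)):
        if net is not None:
            df = net.edges.copy()
            df.insert(0, "split", tag)
            net_frames.append(df)
    _fmt(
        pd.concat(net_frames, ignore_index=True)
        if net_frames
        else pd.DataFrame(columns=["split", "source", "target", "frequency", "retained"]),
        out / "network.tsv",
    )
    kd_frames = []
    for lab, res in key_drivers.items():
        df = key_driver_table(res)
        df.insert(0, "module", lab)
        kd_frames.append(df)
    _fmt(
        pd.concat(kd_frames, ignore_index=True)
        if kd_frames
        else key_driver_table([]).assign(module=pd.Series(dtype=str)),
        out / "keydrivers.tsv",
    )

    return TissueResult(
        tissue=tissue,
        kept_genes=kept,
        split=split,
        dge_discovery=dge_disc,
        dge_test=dge_test,
        asthma_genes=asthma_genes,
        modules=modules,
        enrichment=enrichment,
        eigengene_assoc=eigengene_assoc,
        eqtls=eqtls,
        network_discovery=net_disc,
        network_test=net_test,
        key_drivers=key_drivers,
        validated_drivers=sorted(set(validated)),
        log_cpm=logcpm,
    )


def run_integration(
    config: PipelineConfig,
    pbmc: TissueResult,
    nasal: TissueResult,
    samples: pd.DataFrame,
    out_dir: str | Path | None = None,
) -> list[mediation.MediationResult]:
    """Mediation screen between validated PBMC and nasal key drivers."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not pbmc.validated_drivers or not nasal.validated_drivers:
        logger.warning("no validated key drivers in one or both tissues; empty report")
        results: list[mediation.MediationResult] = []
    else:
        samples = samples.set_index("sample_id").loc[pbmc.log_cpm.columns].reset_index()
        results = mediation.mediation_screen(
            pbmc.validated_drivers,
            nasal.validated_drivers,
            pbmc.log_cpm,
            nasal.log_cpm,
            samples,
            alpha=config.mediation_alpha,
        )
    _fmt(mediation_table(results), out / "mediation.tsv")
    return results


def run_all(config: PipelineConfig) -> dict:
    """Both tissue pipelines plus integration; returns all stage outputs."""
    samples = read_samples(config.samples)
    results = {t: run_tissue(config, t) for t in config.tissues}
    med = run_integration(config, results["pbmc"], results["nasal"], samples)
    return {"tissues": results, "mediation": med}
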