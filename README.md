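# keynet

Two-tissue transcriptome causal-network analysis toolkit. Given RNA-seq count
matrices for two tissues (e.g. PBMC and nasal epithelium), a phenotype/covariate
table, genotype dosages and gene annotation, `keynet` runs the full
discovery/test-validated analysis chain:

1. **preprocess** — CPM normalization (library sizes from the pre-filter
   matrix), low-abundance filtering (remove genes with CPM ≤ 5 in > 10% of
   samples), random 2:1 discovery/test split, cohort summary tables with
   Fisher's exact p-values for binary traits.
2. **diffexpr** — per-gene negative-binomial Wald GLMs (log-library offset,
   IRLS, per-gene ML dispersion with a quasi-likelihood scale guard), BH
   correction, and directional validation of discovery hits in the test set.
3. **coexpression** — unsigned WGCNA-style networks (|pearson|^β adjacency,
   topological overlap, average-linkage clustering with a static cut),
   module eigengenes, hypergeometric module enrichment for validated genes,
   and logistic eigengene–phenotype association.
4. **eqtl** — MAF filtering, genotype PCs, and cis-eQTL mapping (OLS of
   log-CPM on dosage + covariates within ±1 Mb of TSS/TES, BH across pairs).
5. **causalnet** — per-gene 3-state K-means discretization, BIC-scored
   discrete Bayesian networks with an eQTL orientation prior, structure
   sampling by independent Metropolis–Hastings chains (numba-accelerated,
   with a pure-Python reference engine), and a ≥ 30% edge-frequency
   consensus network.
6. **keydriver** — key driver analysis: enrichment of module members in
   k-step directed downstream neighborhoods (k = 1..7) against the K-step
   subnetwork background, with discovery/test validation.
7. **mediation** — three-regression causal mediation (robust SEs, Sobel,
   percentile bootstrap, mediator-permutation test) screened across
   key-driver pairs in both directions with per-direction BH correction.
8. **synthetic_data** — a two-tissue cohort generator with planted DE genes,
   causal modules with designated key-driver roots, cis-eQTLs, and a
   cross-tissue mediation chain, plus a machine-readable truth set used by
   the recovery test-suite.
9. **pipeline** — end-to-end orchestration with deterministic per-stage
   seeds and TSV artifacts for every stage.

## Test

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests, and
`tests/test_acceptance.py` (one test per acceptance criterion: printed-cohort
arithmetic, exact-test oracles, 25-DAG enumeration vs MCMC, consensus
boundaries, key-driver and mediation recovery on planted cohorts, stage
calibration, and end-to-end determinism).

## CLI

```bash
keynet simulate --config sim.yaml --out cohort/ --seed 1
keynet preprocess --counts cohort/counts_pbmc.tsv --samples cohort/samples.tsv --out pre/ --seed 1
keynet dge --counts counts.tsv --samples samples.tsv --covariates age,sex,race --out dge.tsv
keynet modules --counts counts.tsv --beta auto --min-size 30 --out modules.tsv
keynet eqtl --counts counts.tsv --vcf geno.vcf --annotation ann.tsv --samples samples.tsv \
            --window 1000000 --pcs 3 --out eqtl.tsv
keynet bayesnet --counts counts.tsv --anchors eqtl_genes.txt --networks 100 \
                --threshold 0.3 --lambda 0.693 --seed 1 --out network.tsv
keynet kda --network network.tsv --module members.txt --k 7 --out kda.tsv
keynet run --config pipeline.yaml
```

The pipeline config is a flat YAML mapping of `keynet.pipeline.PipelineConfig`
fields (input paths plus stage parameters; published thresholds are the
defaults: CPM ≤ 5 / > 10% filter, BH 0.05, 1 Mb cis window, MAF ≥ 0.01,
3 expression states, 30% consensus, K = 7).

## Data formats

Tab-separated text with header rows throughout (gene IDs in the first column
of count matrices); genotypes as minimal VCF v4.2 (biallelic, GT-only); truth
sets as JSON. `keynet.synthetic_data.write_cohort` / `read_cohort` round-trip
a full cohort losslessly.
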