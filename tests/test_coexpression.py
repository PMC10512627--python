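"""coexpression: TOM, module detection, eigengenes, enrichment, association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from keynet.coexpression import (
    UNASSIGNED,
    associate_eigengenes,
    build_tom,
    compute_eigengene,
    detect_modules,
    enrich_modules,
)


def block_model(rng, n_blocks=2, block=50, n_bg=0, n_samples=200, within=0.8):
    """Factor model: within-block correlation ~ `within`, cross-block zero."""
    rows = []
    labels = []
    for b in range(n_blocks):
        factor = rng.normal(size=n_samples)
        lam = np.sqrt(within)
        for _ in range(block):
            rows.append(lam * factor + np.sqrt(1 - within) * rng.normal(size=n_samples))
            labels.append(b)
    for _ in range(n_bg):
        rows.append(rng.normal(size=n_samples))
        labels.append(-1)
    return np.array(rows), np.array(labels)


class TestTom:
    def test_perfect_pair_beta_one(self, rng):
        x = rng.normal(size=50)
        tom = build_tom(np.vstack([x, 2 * x + 3]), beta=1)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_single_edge_tom_equals_adjacency(self, rng):
        # two correlated genes + one independent: TOM of the pair ~ adjacency
        x = rng.normal(size=2000)
        z = rng.normal(size=2000)
        expr = np.vstack([x, x + 0.1 * rng.normal(size=2000), z])
        corr = abs(np.corrcoef(expr[0], expr[1])[0, 1])
        tom = build_tom(expr, beta=6)
        assert tom[0, 1] == pytest.approx(corr**6, abs=0.01)

    def test_independent_genes_small_tom(self, rng):
        expr = rng.normal(size=(40, 1000))
        tom = build_tom(expr, beta=6)
        off = tom[np.triu_indices_from(tom, 1)]
        assert off.mean() < 0.05

    def test_range_and_symmetry(self, rng):
        expr = rng.normal(size=(25, 60))
        tom = build_tom(expr, beta=6)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1

    def test_constant_gene_warns(self, rng):
        expr = np.vstack([np.ones(30), rng.normal(size=30)])
        with pytest.warns(UserWarning):
            tom = build_tom(expr, beta=2)
        assert tom[0, 1] == 0.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            build_tom(np.ones((3, 2)), beta=2)


class TestDetectModules:
    def test_recovers_planted_blocks(self, rng):
        from sklearn.metrics import adjusted_rand_score

        expr, labels = block_model(rng, n_blocks=2, block=50, n_bg=30)
        tom = build_tom(expr, beta=6)
        assign = detect_modules(tom, expr=expr, min_module_size=30)
        found = np.array([assign[f"g{i}"] for i in range(len(labels))])
        in_block = labels >= 0
        assert adjusted_rand_score(labels[in_block], found[in_block]) >= 0.95
        assert len({m for m in found[in_block] if m != UNASSIGNED}) == 2

    def test_block_recovery_across_seeds(self):
        from sklearn.metrics import adjusted_rand_score

        successes = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            expr, labels = block_model(rng, n_blocks=2, block=40, within=0.7, n_samples=150)
            tom = build_tom(expr, beta=6)
            assign = detect_modules(tom, expr=expr, min_module_size=30)
            found = [assign[f"g{i}"] for i in range(len(labels))]
            n_modules = len({m for m in found if m != UNASSIGNED})
            if n_modules == 2 and adjusted_rand_score(labels, found) >= 0.95:
                successes += 1
        assert successes >= 18

    def test_independent_genes_no_modules(self, rng):
        expr = rng.normal(size=(80, 300))
        tom = build_tom(expr, beta=6)
        assign = detect_modules(tom, expr=expr, min_module_size=30)
        assert set(assign.values()) == {UNASSIGNED}

    def test_gene_order_invariance(self, rng):
        expr, _ = block_model(rng, n_blocks=2, block=40, n_bg=10)
        tom = build_tom(expr, beta=6)
        base = detect_modules(tom, expr=expr)
        perm = rng.permutation(expr.shape[0])
        tom_p = build_tom(expr[perm], beta=6)
        permuted = detect_modules(
            tom_p, expr=expr[perm], gene_ids=[f"g{i}" for i in perm]
        )
        # same partition up to labels
        from collections import defaultdict

        groups_a, groups_b = defaultdict(set), defaultdict(set)
        for g, m in base.items():
            groups_a[m].add(g)
        for g, m in permuted.items():
            groups_b[m].add(g)
        assert set(map(frozenset, groups_a.values())) == set(map(frozenset, groups_b.values()))


class TestEigengene:
    def test_identical_genes(self, rng):
        x = rng.normal(size=40)
        eig = compute_eigengene(np.vstack([x, x, x]))
        z = (x - x.mean()) / x.std()
        z = z / np.linalg.norm(z)
        assert np.allclose(np.abs(eig), np.abs(z), atol=1e-8)
        assert np.corrcoef(eig, x)[0, 1] > 0  # orientation

    def test_sign_flip_invariance(self, rng):
        expr = rng.normal(size=(10, 30))
        a = compute_eigengene(expr)
        b = compute_eigengene(-expr)
        assert np.allclose(a, b, atol=1e-10) or np.allclose(a, -b, atol=1e-10)
        # orientation invariant: correlation with module average is >= 0
        assert a @ ((expr - expr.mean(1, keepdims=True)) / expr.std(1, keepdims=True)).mean(0) >= 0

    def test_variance_explained_is_maximal(self, rng):
        expr = rng.normal(size=(15, 50)) + rng.normal(size=(1, 50))
        sd = expr.std(axis=1, keepdims=True)
        z = (expr - expr.mean(axis=1, keepdims=True)) / sd
        eig = compute_eigengene(expr)
        explained = np.sum((z @ eig) ** 2)
        # SVD oracle: no direction explains more
        _, s, _ = np.linalg.svd(z, full_matrices=False)
        assert explained == pytest.approx(s[0] ** 2, rel=1e-8)
        for _ in range(20):
            v = rng.normal(size=50)
            v /= np.linalg.norm(v)
            assert np.sum((z @ v) ** 2) <= explained + 1e-8

    def test_degenerate_modules(self):
        with pytest.raises(ValueError):
            compute_eigengene(np.ones((3, 10)))
        with pytest.raises(ValueError):
            compute_eigengene(np.ones((1, 10)) * np.arange(10))


class TestEnrichment:
    def test_exact_match_module(self):
        universe = [f"g{i}" for i in range(100)]
        asthma = set(universe[:10])
        assign = {g: ("mod1" if g in asthma else UNASSIGNED) for g in universe}
        res = enrich_modules(assign, asthma, universe)
        assert res[0].fold_enrichment == pytest.approx(10.0)  # universe/target
        assert res[0].is_asthma_module

    def test_disjoint_module_not_flagged(self):
        universe = [f"g{i}" for i in range(100)]
        assign = {g: ("mod1" if i >= 50 else UNASSIGNED) for i, g in enumerate(universe)}
        res = enrich_modules(assign, set(universe[:10]), universe)
        assert res[0].fold_enrichment == 0.0
        assert not res[0].is_asthma_module

    def test_planted_module_ranked_first(self, small_cohort):
        truth = small_cohort.truth
        assign = dict(truth.module_membership["pbmc"])
        universe = list(small_cohort.counts["pbmc"].gene_ids)
        for g in universe:
            assign.setdefault(g, UNASSIGNED)
        de = set(truth.de_genes["pbmc"])
        res = enrich_modules(assign, de, universe)
        assert res[0].module == "mod0"
        assert res[0].is_asthma_module

    def test_subset_violation(self):
        with pytest.raises(ValueError):
            enrich_modules({"a": "mod1"}, {"zzz"}, {"a", "b"})

    def test_empty_modules(self):
        assert enrich_modules({"a": UNASSIGNED}, set(), {"a"}) == []


class TestAssociation:
    @staticmethod
    def samples_frame(y, rng):
        n = len(y)
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "asthma": y,
                "age": rng.normal(12, 3, n),
                "sex": rng.choice(["F", "M"], n),
                "race": rng.choice(["A", "B"], n),
            }
        )

    def test_null_pvalues_uniform(self):
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, 120)
            eig = rng.normal(size=120)
            res = associate_eigengenes({"m": eig}, self.samples_frame(y, rng))
            pvals.append(res[0].p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_liability_significant(self, small_cohort):
        rng = np.random.default_rng(0)
        y = small_cohort.samples["asthma"].to_numpy()
        liability_like = y + 0.3 * rng.normal(size=len(y))
        res = associate_eigengenes(
            {"m": liability_like}, small_cohort.samples, covariates=("age", "sex", "race")
        )
        assert res[0].fdr <= 0.05

    def test_constant_eigengene_flagged(self, rng):
        y = rng.integers(0, 2, 60)
        res = associate_eigengenes({"m": np.ones(60)}, self.samples_frame(y, rng))
        assert res[0].flagged
        assert res[0].p == 1.0
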