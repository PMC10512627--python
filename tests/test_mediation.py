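"""mediation: three-regression identities, Sobel/bootstrap/permutation
calibration, and the screen's direction asymmetry."""

import numpy as np
import pytest
from scipy import stats as sps

from keynet.mediation import (
    bootstrap_indirect,
    fit_mediation,
    mediation_screen,
    permutation_test,
)
from keynet.preprocess import log_cpm
from keynet.synthetic_data import SimConfig, generate_cohort


def chain(rng, n=300, a=1.0, b=1.0, noise=0.1):
    x = rng.normal(size=n)
    m = a * x + noise * rng.normal(size=n)
    y = b * m + noise * rng.normal(size=n)
    return x, m, y


class TestFitMediation:
    def test_noise_free_chain(self, rng):
        # m == x exactly makes (b, c') unidentifiable, so use a vanishing
        # perturbation to keep the design full rank
        x = rng.normal(size=100)
        m = x + 1e-6 * rng.normal(size=100)
        y = m.copy()
        res = fit_mediation(x, m, y)
        assert res.a == pytest.approx(1.0, abs=1e-5)
        assert res.b == pytest.approx(1.0, abs=1e-3)
        assert res.c_prime == pytest.approx(0.0, abs=1e-3)
        assert res.indirect == pytest.approx(1.0, abs=1e-3)

    def test_linear_identity(self, rng):
        for _ in range(5):
            x = rng.normal(size=80)
            m = rng.normal(size=80)
            y = rng.normal(size=80)
            cov = rng.normal(size=(80, 2))
            res = fit_mediation(x, m, y, covariates=cov)
            assert res.c == pytest.approx(res.c_prime + res.indirect, abs=1e-10)

    def test_null_sobel_uniform(self):
        # x independent of (m, y) but with a live m -> y path: the Sobel z
        # then behaves like the z of the a-path and its p-value is uniform
        # (at a = b = 0 the Sobel statistic is conservative by construction)
        pvals = []
        for seed in range(500):
            r = np.random.default_rng(seed)
            x = r.normal(size=60)
            m = r.normal(size=60)
            y = m + 0.5 * r.normal(size=60)
            pvals.append(fit_mediation(x, m, y).sobel_p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_input_validation(self, rng):
        x = rng.normal(size=40)
        with pytest.raises(ValueError, match="n >= 30"):
            fit_mediation(x[:10], x[:10], x[:10])
        with pytest.raises(ValueError, match="constant"):
            fit_mediation(np.ones(40), x, x)
        with pytest.raises(ValueError, match="aligned"):
            fit_mediation(x, x[:20], x)


class TestBootstrap:
    def test_noise_free_collapse(self, rng):
        x = rng.normal(size=60)
        m = x + 1e-6 * rng.normal(size=60)
        lo, hi = bootstrap_indirect(x, m, m.copy(), B=200, seed=1)
        assert lo == pytest.approx(1.0, abs=5e-3)
        assert hi == pytest.approx(1.0, abs=5e-3)

    def test_seed_reproducible(self, rng):
        x, m, y = chain(rng, n=80, noise=0.5)
        ci1 = bootstrap_indirect(x, m, y, B=100, seed=7)
        ci2 = bootstrap_indirect(x, m, y, B=100, seed=7)
        assert ci1 == ci2

    def test_null_coverage(self):
        covered = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            x = r.normal(size=60)
            m = r.normal(size=60)
            y = r.normal(size=60)
            lo, hi = bootstrap_indirect(x, m, y, B=150, seed=seed)
            covered += lo <= 0 <= hi
        assert 0.88 <= covered / 200 <= 1.0


class TestPermutation:
    def test_strong_chain_minimal_p(self, rng):
        x, m, y = chain(rng, n=300, a=1.0, b=1.0, noise=0.1)
        p = permutation_test(x, m, y, iterations=199, seed=3)
        assert p == pytest.approx(1 / 200)

    def test_zero_iterations(self, rng):
        x, m, y = chain(rng)
        assert permutation_test(x, m, y, iterations=0) == 1.0

    def test_null_mean_half(self):
        ps = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            x = r.normal(size=50)
            m = r.normal(size=50)
            y = r.normal(size=50)
            ps.append(permutation_test(x, m, y, iterations=49, seed=seed))
        assert abs(np.mean(ps) - 0.5) <= 0.05

    def test_rank_agreement_with_sobel(self, rng):
        # weak-effect grid at small n so neither p-value saturates
        sobel, perm = [], []
        for i, a in enumerate(np.linspace(0.0, 0.45, 10)):
            x = rng.normal(size=60)
            m = a * x + rng.normal(size=60)
            y = a * m + rng.normal(size=60)
            res = fit_mediation(x, m, y)
            sobel.append(res.sobel_p)
            perm.append(permutation_test(x, m, y, iterations=499, seed=i))
        rho = sps.spearmanr(sobel, perm).statistic
        assert rho >= 0.9


class TestScreen:
    def test_direction_asymmetry_on_planted_chain(self):
        fwd = rev = 0
        n_seeds = 10
        for seed in range(n_seeds):
            c = generate_cohort(SimConfig(n_samples=300, n_genes_per_tissue=300, seed=seed))
            tr = c.truth
            x, m = tr.mediation["x_gene"], tr.mediation["m_gene"]
            res = mediation_screen(
                [x], [m], log_cpm(c.counts["pbmc"]), log_cpm(c.counts["nasal"]), c.samples
            )
            f = next(r for r in res if r.direction == "pbmc->nasal")
            r_ = next(r for r in res if r.direction == "nasal->pbmc")
            fwd += f.fdr <= 0.05
            rev += r_.fdr <= 0.05
        assert fwd / n_seeds >= 0.8
        assert rev / n_seeds <= 0.1

    def test_swapping_roles_breaks_significance(self, rng):
        x, m, y = chain(rng, n=300, a=0.7, b=0.7, noise=0.5)
        fwd = fit_mediation(x, m, y)
        rev = fit_mediation(m, x, y)
        assert fwd.sobel_p < 1e-4
        assert rev.sobel_p > fwd.sobel_p

    def test_null_cohort_type_one(self, null_cohort):
        tr = null_cohort.truth
        pb = tr.key_drivers["pbmc/mod0"] + tr.key_drivers["pbmc/mod1"]
        ns = tr.key_drivers["nasal/mod0"] + tr.key_drivers["nasal/mod1"]
        res = mediation_screen(
            pb, ns, log_cpm(null_cohort.counts["pbmc"]), log_cpm(null_cohort.counts["nasal"]),
            null_cohort.samples,
        )
        raw_rate = np.mean([r.sobel_p <= 0.05 for r in res])
        assert raw_rate <= 0.15  # single small cohort; acceptance suite tightens this

    def test_empty_driver_list_warns(self, null_cohort):
        with pytest.warns(UserWarning):
            out = mediation_screen(
                [], ["NS00000"], log_cpm(null_cohort.counts["pbmc"]),
                log_cpm(null_cohort.counts["nasal"]), null_cohort.samples,
            )
        assert out == []

    def test_single_perfect_pair_significant(self, rng):
        import pandas as pd

        n = 200
        x, m, y = chain(rng, n=n, a=0.8, b=0.8, noise=0.3)
        samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)], "asthma": (y > np.median(y)).astype(int)})
        pe = pd.DataFrame([x], index=["X"])
        ne = pd.DataFrame([m], index=["M"])
        res = mediation_screen(["X"], ["M"], pe, ne, samples)
        f = next(r for r in res if r.direction == "pbmc->nasal")
        assert f.fdr <= 0.05
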