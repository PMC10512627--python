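"""causalnet: discretization, scoring against hand values and the 25-DAG
enumeration oracle, MCMC behavior, consensus thresholding."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from keynet.causalnet import (
    DiscretizedMatrix,
    EqtlPrior,
    _Scorer,
    consensus,
    discretize,
    mcmc_sample,
    score_network,
)


def all_three_node_dags(nodes=("X", "Y", "Z")):
    pairs = [(a, b) for a in nodes for b in nodes if a != b]
    dags = []
    for mask in range(2**6):
        edges = [pairs[i] for i in range(6) if mask >> i & 1]
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if nx.is_directed_acyclic_graph(g):
            dags.append(edges)
    return dags


def chain_data(rng, n=500, flip=0.15):
    x = rng.integers(0, 3, n)
    y = (x + (rng.random(n) < flip)) % 3
    z = (y + (rng.random(n) < flip)) % 3
    return DiscretizedMatrix(states=np.vstack([x, y, z]), gene_ids=["X", "Y", "Z"])


class TestDiscretize:
    def test_separated_clusters(self):
        vals = np.array([0.0] * 10 + [5.0] * 10 + [10.0] * 10)
        d = discretize(vals.reshape(1, -1), seed=0)
        assert list(d.states[0][::10]) == [0, 1, 2]

    def test_constant_gene_all_zero(self):
        d = discretize(np.zeros((1, 20)), seed=0)
        assert (d.states == 0).all()

    def test_two_distinct_values(self):
        vals = np.array([1.0, 2.0] * 10)
        d = discretize(vals.reshape(1, -1), seed=0)
        assert set(d.states[0]) == {0, 1}
        assert (d.states[0] == (vals == 2.0).astype(int)).all()

    def test_affine_equivariance(self, rng):
        vals = rng.normal(size=(1, 60))
        a = discretize(vals, seed=5)
        b = discretize(3.5 * vals + 11.0, seed=5)
        assert (a.states == b.states).all()

    def test_states_ordered_by_mean(self, rng):
        vals = rng.normal(size=(5, 100))
        d = discretize(vals, seed=1)
        for gi in range(5):
            means = [vals[gi][d.states[gi] == s].mean() for s in range(3)]
            assert means == sorted(means)


class TestScore:
    def test_single_node_hand_value(self):
        # n = 3 samples, one in each state: logL = 3 ln(1/3), penalty ln 3
        data = DiscretizedMatrix(states=np.array([[0, 1, 2]]), gene_ids=["A"])
        score = score_network([], data, EqtlPrior(kappa=0.0, lam=0.0))
        assert score == pytest.approx(-4 * math.log(3), abs=1e-12)

    def test_empty_graph_decomposes(self, rng):
        states = rng.integers(0, 3, size=(4, 100))
        data = DiscretizedMatrix(states=states, gene_ids=list("ABCD"))
        prior = EqtlPrior(kappa=0.0, lam=0.0)
        total = score_network([], data, prior)
        parts = sum(
            score_network([], DiscretizedMatrix(states=states[[i]], gene_ids=[g]), prior)
            for i, g in enumerate("ABCD")
        )
        assert total == pytest.approx(parts, abs=1e-9)

    def test_strong_dependence_beats_empty(self, rng):
        n = 500
        x = rng.integers(0, 3, n)
        y = (x + (rng.random(n) < 0.1)) % 3
        data = DiscretizedMatrix(states=np.vstack([x, y]), gene_ids=["X", "Y"])
        prior = EqtlPrior(kappa=0.0, lam=0.0)
        assert score_network([("X", "Y")], data, prior) > score_network([], data, prior)

    def test_cycle_rejected(self, rng):
        data = DiscretizedMatrix(states=rng.integers(0, 3, size=(2, 30)), gene_ids=["A", "B"])
        with pytest.raises(ValueError, match="cycle"):
            score_network([("A", "B"), ("B", "A")], data)

    def test_single_edge_delta_is_local(self, rng):
        """Decomposability: full-rescore delta equals the affected family delta."""
        states = rng.integers(0, 3, size=(5, 200))
        data = DiscretizedMatrix(states=states, gene_ids=list("ABCDE"))
        prior = EqtlPrior(anchored={"A"}, kappa=0.7, lam=0.4)
        base_edges = [("A", "B"), ("B", "C"), ("A", "D")]
        new_edges = base_edges + [("D", "E")]
        full_delta = score_network(new_edges, data, prior) - score_network(base_edges, data, prior)
        scorer = _Scorer(data, prior)
        local = scorer.family(4, (3,)) - scorer.family(4, ()) + scorer.edge_prior(3, 4)
        assert full_delta == pytest.approx(local, abs=1e-9)

    def test_markov_equivalence_and_anchor_breaking(self, rng):
        data = chain_data(rng)
        flat = EqtlPrior(kappa=0.0, lam=0.0)
        s1 = score_network([("X", "Y"), ("Y", "Z")], data, flat)
        s2 = score_network([("Y", "X"), ("Y", "Z")], data, flat)
        s3 = score_network([("Z", "Y"), ("Y", "X")], data, flat)
        assert s1 == pytest.approx(s2, abs=1e-9)
        assert s1 == pytest.approx(s3, abs=1e-9)
        anchored = EqtlPrior(anchored={"X"}, kappa=0.0, lam=math.log(2))
        assert score_network([("X", "Y"), ("Y", "Z")], data, anchored) > score_network(
            [("Y", "X"), ("Y", "Z")], data, anchored
        )


class TestMcmc:
    def test_independent_pair_low_edge_frequency(self, rng):
        x = rng.integers(0, 3, 500)
        y = rng.integers(0, 3, 500)
        data = DiscretizedMatrix(states=np.vstack([x, y]), gene_ids=["A", "B"])
        nets = mcmc_sample(data, EqtlPrior(kappa=1.0, lam=0.0), n_networks=100, sweeps=400, seed=3)
        freq = np.mean([len(s) > 0 for s in nets])
        assert freq <= 0.2

    def test_planted_chain_consensus_recovery(self):
        successes = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = chain_data(rng)
            nets = mcmc_sample(
                data,
                EqtlPrior(anchored={"X"}, kappa=1.0, lam=math.log(2)),
                n_networks=100,
                sweeps=600,
                seed=seed + 1000,
            )
            retained = set(consensus(nets, 0.3).retained_edges())
            if {("X", "Y"), ("Y", "Z")} <= retained:
                successes += 1
        assert successes >= 19

    def test_most_frequent_graph_matches_enumeration(self):
        from collections import Counter

        successes = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            data = chain_data(rng)
            prior = EqtlPrior(anchored={"X"}, kappa=1.0, lam=math.log(2))
            best = max(
                (tuple(sorted(d)) for d in all_three_node_dags()),
                key=lambda d: score_network(list(d), data, prior),
            )
            nets = mcmc_sample(data, prior, n_networks=100, sweeps=600, seed=seed + 2000)
            most_common = Counter(tuple(sorted(s)) for s in nets).most_common(1)[0][0]
            if most_common == best:
                successes += 1
        assert successes >= 18

    def test_engines_agree_statistically(self, rng):
        data = chain_data(rng)
        prior = EqtlPrior(anchored={"X"}, kappa=1.0, lam=math.log(2))
        fast = mcmc_sample(data, prior, n_networks=150, sweeps=2000, seed=5)
        ref = mcmc_sample(data, prior, n_networks=150, sweeps=2000, seed=5, engine="python")
        for edge in [("X", "Y"), ("Y", "Z"), ("Y", "X")]:
            f = np.mean([edge in s for s in fast])
            r = np.mean([edge in s for s in ref])
            assert abs(f - r) < 0.15

    def test_max_parents_respected(self, rng):
        states = rng.integers(0, 3, size=(6, 200))
        data = DiscretizedMatrix(states=states, gene_ids=list("ABCDEF"))
        nets = mcmc_sample(data, EqtlPrior(kappa=0.0, lam=0.0), n_networks=10, sweeps=3000, seed=2, max_parents=2)
        for s in nets:
            indeg = {}
            g = nx.DiGraph(list(s))
            assert nx.is_directed_acyclic_graph(g)
            for _, v in s:
                indeg[v] = indeg.get(v, 0) + 1
            assert max(indeg.values(), default=0) <= 2

    def test_deterministic_given_seed(self, rng):
        data = chain_data(rng)
        a = mcmc_sample(data, n_networks=5, sweeps=300, seed=9)
        b = mcmc_sample(data, n_networks=5, sweeps=300, seed=9)
        assert a == b


class TestConsensus:
    def fake_samples(self, count, total):
        return [{("a", "b")} if i < count else set() for i in range(total)]

    def test_boundary_300_of_1000(self):
        net = consensus(self.fake_samples(300, 1000), threshold=0.30)
        assert net.edges.iloc[0]["retained"]

    def test_299_dropped(self):
        net = consensus(self.fake_samples(299, 1000), threshold=0.30)
        assert not net.edges.iloc[0]["retained"]

    def test_always_present(self):
        net = consensus(self.fake_samples(1000, 1000), threshold=0.30)
        assert net.edges.iloc[0]["frequency"] == 1.0

    def test_monotone_in_threshold(self, rng):
        samples = []
        for _ in range(50):
            samples.append({("a", "b")} if rng.random() < 0.6 else {("b", "c")})
        sizes = [
            len(consensus(samples, threshold=t).retained_edges()) for t in (0.1, 0.3, 0.5, 0.9)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            consensus([])
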