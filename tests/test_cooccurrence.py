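"""Spearman thresholding, strict edge rules, accounting, and planted-block
recovery for the multi-domain co-occurrence networks."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from benthicom import (
    CommunityTable,
    account_network,
    build_network,
    spearman_matrix,
)
from benthicom.cooccurrence import SpearmanResult
import networkx as nx


def _table(counts, domain, prefix):
    counts = np.asarray(counts)
    return CommunityTable(pd.DataFrame(
        counts, index=[f"S{i}" for i in range(counts.shape[0])],
        columns=[f"{prefix}{j}" for j in range(counts.shape[1])]),
        domain=domain)


def _stub_result(rho, p, domains):
    nodes = list(domains.keys())
    return SpearmanResult(
        rho=pd.DataFrame(rho, index=nodes, columns=nodes),
        p=pd.DataFrame(p, index=nodes, columns=nodes),
        domains=pd.Series(domains), n_samples=6)


class TestSpearman:
    def test_monotone_pair_is_one(self):
        # constant row totals so relative abundances preserve the count ranks
        a = np.arange(1, 7)
        b = 2 * a
        filler = 100 - a - b
        t = _table(np.column_stack([a, b, filler]), "bacteria", "b")
        res = spearman_matrix([t])
        assert res.rho.loc["bacteria:b0", "bacteria:b1"] == pytest.approx(1.0)

    def test_reversed_pair_is_minus_one(self):
        a = np.arange(1, 7)
        b = 7 - a
        t = _table(np.column_stack([a, b, np.full(6, 10)]), "bacteria", "b")
        res = spearman_matrix([t])
        assert res.rho.loc["bacteria:b0", "bacteria:b1"] == pytest.approx(-1.0)

    def test_constant_taxon_excluded(self):
        counts = np.column_stack([np.arange(1, 7), np.full(6, 4)])
        # relative abundances make neither column constant; force one by
        # a genuinely constant profile across samples
        t = _table(np.column_stack([counts, counts.sum(axis=1)]),
                   "fungi", "f")
        res = spearman_matrix([t])
        assert all(n.startswith("fungi:") for n in res.rho.index)

    def test_matches_rank_then_pearson_brute_force(self):
        rng = np.random.default_rng(0)
        t = _table(rng.integers(1, 200, size=(12, 20)), "protist", "p")
        res = spearman_matrix([t], exact_p=False)
        rel = t.relative_abundance().to_numpy()
        for _ in range(20):
            i, j = rng.choice(20, 2, replace=False)
            ri, rj = rankdata(rel[:, i]), rankdata(rel[:, j])
            expected = np.corrcoef(ri, rj)[0, 1]
            got = res.rho.loc[f"protist:p{i}", f"protist:p{j}"]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_mismatched_sample_sets_rejected(self):
        a = _table(np.ones((6, 2), dtype=int), "bacteria", "b")
        b = CommunityTable(pd.DataFrame(
            np.ones((6, 2), dtype=int),
            index=[f"X{i}" for i in range(6)], columns=["f0", "f1"]),
            domain="fungi")
        with pytest.raises(Exception):
            spearman_matrix([a, b])


class TestBuildNetwork:
    def test_rho_exactly_at_threshold_not_retained(self):
        rho = np.array([[1.0, 0.8], [0.8, 1.0]])
        p = np.array([[0.0, 0.001], [0.001, 0.0]])
        res = _stub_result(rho, p, {"bacteria:a": "bacteria",
                                    "bacteria:b": "bacteria"})
        net = build_network(res, rho_threshold=0.8, alpha=0.05)
        assert net.number_of_edges() == 0

    def test_rho_above_threshold_retained(self):
        rho = np.array([[1.0, 0.80001], [0.80001, 1.0]])
        p = np.array([[0.0, 0.001], [0.001, 0.0]])
        res = _stub_result(rho, p, {"bacteria:a": "bacteria",
                                    "bacteria:b": "bacteria"})
        net = build_network(res, 0.8, 0.05)
        assert net.number_of_edges() == 1

    def test_p_at_alpha_not_retained(self):
        rho = np.array([[1.0, 0.95], [0.95, 1.0]])
        p = np.array([[0.0, 0.05], [0.05, 0.0]])
        res = _stub_result(rho, p, {"bacteria:a": "bacteria",
                                    "bacteria:b": "bacteria"})
        assert build_network(res, 0.8, 0.05).number_of_edges() == 0

    def test_identical_rank_order_planted_pair_retained(self):
        rng = np.random.default_rng(1)
        base = rng.permutation(np.arange(1, 13)) * 10
        counts = np.column_stack([base, base + rng.integers(0, 2, 12),
                                  rng.integers(1, 100, 12)])
        t = _table(counts, "bacteria", "b")
        res = spearman_matrix([t])
        net = build_network(res, 0.8, 0.05)
        assert net.has_edge("bacteria:b0", "bacteria:b1")

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(2)
        t = _table(rng.integers(1, 100, size=(12, 15)), "bacteria", "b")
        res = spearman_matrix([t])
        counts = [build_network(res, thr, 0.05).number_of_edges()
                  for thr in (0.5, 0.7, 0.9)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_invariant_to_sample_and_taxon_relabeling(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 100, size=(12, 10))
        t1 = _table(counts, "bacteria", "b")
        n1 = build_network(spearman_matrix([t1]), 0.6, 0.05)
        perm = rng.permutation(12)
        t2 = CommunityTable(t1.data.iloc[perm], "bacteria")
        n2 = build_network(spearman_matrix([t2]), 0.6, 0.05)
        assert sorted(map(tuple, map(sorted, n1.edges))) == \
            sorted(map(tuple, map(sorted, n2.edges)))

    def test_null_edge_count_matches_permutation_estimate(self):
        # independent noise: observed edges vs a Monte-Carlo estimate of
        # P(edge) for unrelated taxa at the same n
        rng = np.random.default_rng(4)
        n, k = 12, 25
        t = _table(rng.integers(1, 1000, size=(n, k)), "bacteria", "b")
        res = spearman_matrix([t])
        observed = build_network(res, 0.8, 0.05).number_of_edges()
        hits = 0
        reps = 4000
        base = rankdata(rng.random(n))
        base = (base - base.mean()) / np.sqrt(((base - base.mean()) ** 2).sum())
        for _ in range(reps):
            y = rng.permutation(base)
            r = float(base @ y)
            if abs(r) > 0.8:
                hits += 1
        p_edge = hits / reps
        n_pairs = k * (k - 1) / 2
        expect = n_pairs * p_edge
        sigma = max(np.sqrt(expect), 1.0)
        assert abs(observed - expect) <= 3 * sigma


class TestAccounting:
    def test_empty_network_all_zero(self):
        acct = account_network(nx.Graph())
        assert acct.total_edges == 0
        assert all(v == 0 for v in acct.nodes_per_domain.values())

    def test_hand_built_five_edge_network(self):
        g = nx.Graph()
        doms = {"b1": "bacteria", "b2": "bacteria", "b3": "bacteria",
                "p1": "protist", "p2": "protist"}
        edges = [("b1", "b2"), ("b2", "b3"), ("p1", "p2"),
                 ("b1", "p1"), ("b3", "p2")]
        for u, v in edges:
            g.add_edge(u, v, rho=0.9, p=0.01, sign=1)
        for n, d in doms.items():
            g.nodes[n]["domain"] = d
        acct = account_network(g)
        assert acct.intra_edges == {"bacteria": 2, "fungi": 0, "protist": 1}
        assert acct.inter_edges[("bacteria", "protist")] == 2
        assert acct.inter_edges[("bacteria", "fungi")] == 0
        assert acct.nodes_per_domain == {"bacteria": 3, "fungi": 0,
                                         "protist": 2}

    def test_intra_plus_inter_equals_total(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = nx.Graph()
            nodes = [(f"n{i}", rng.choice(["bacteria", "fungi", "protist"]))
                     for i in range(12)]
            for n, d in nodes:
                g.add_node(n, domain=str(d))
            for _ in range(rng.integers(1, 20)):
                u, v = rng.choice(12, 2, replace=False)
                g.add_edge(f"n{u}", f"n{v}", rho=0.9, p=0.01, sign=1)
            g.remove_nodes_from(list(nx.isolates(g)))
            acct = account_network(g)
            assert acct.total_edges == g.number_of_edges()


class TestPlantedBlocks:
    def test_cross_domain_planted_pairs_recovered(self):
        # three planted cross-domain pairs at latent correlation 0.95, n=12;
        # each table gets a filler column fixing row totals so relative
        # abundances preserve the planted count ranks
        rng = np.random.default_rng(6)
        n = 12
        z = rng.normal(size=(n, 3))
        noise = np.sqrt(1 - 0.95 ** 2)

        def derived(latent):
            return latent * 0.95 + rng.normal(size=n) * noise

        def to_counts(x):
            return np.round(200 * (x - x.min() + 0.5)).astype(int) + 1

        def domain_counts(planted):
            cols = [to_counts(v) for v in planted]
            cols += [rng.integers(1, 300, n) for _ in range(8)]
            block = np.column_stack(cols)
            filler = block.sum() // n + 500 - block.sum(axis=1)
            return np.column_stack([block, filler - filler.min() + 1])

        bact = domain_counts([z[:, 0], z[:, 1]])
        fung = domain_counts([derived(z[:, 0]), derived(z[:, 2])])
        prot = domain_counts([derived(z[:, 1]), derived(z[:, 2])])
        tb = _table(bact, "bacteria", "b")
        tf = _table(fung, "fungi", "f")
        tp = _table(prot, "protist", "p")
        net = build_network(spearman_matrix([tb, tf, tp]), 0.8, 0.05)
        assert net.has_edge("bacteria:b0", "fungi:f0")
        assert net.has_edge("bacteria:b1", "protist:p0")
        assert net.has_edge("fungi:f1", "protist:p1")
        acct = account_network(net)
        assert acct.inter_edges[("bacteria", "fungi")] >= 1
        assert acct.inter_edges[("bacteria", "protist")] >= 1
        assert acct.inter_edges[("fungi", "protist")] >= 1
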