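import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    fitch_bruteforce,
    negbin_marginal_quadrature,
    shared_rate_marginal_quadrature,
)
from xenosig import simulate as sim
from xenosig.funcdiv import (
    SiteChangeCounts,
    _log_p0,
    _log_p1,
    critical_sites,
    estimate_type1,
    fitch_site_changes,
    type1_loglik,
)
from xenosig.io import ClusteredAlignment


def make_ca(seqs1, seqs2, newick=None):
    names1 = [f"a{i}" for i in range(len(seqs1))]
    names2 = [f"b{i}" for i in range(len(seqs2))]

    def ladder(names):
        t = names[-1]
        for n in reversed(names[:-1]):
            t = f"({n},{t})"
        return t

    newick = newick or f"({ladder(names1)},{ladder(names2)});"
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    return ClusteredAlignment(
        sequences=dict(zip(names1 + names2, seqs1 + seqs2)),
        tree=tree,
        clusters={n: 1 for n in names1} | {n: 2 for n in names2},
    )


def tree_to_adjacency(node, prefix="n"):
    """dendropy subtree -> (adjacency dict, leaf-name map) for the oracle."""
    adjacency = {}
    counter = [0]

    def walk(nd):
        if nd.is_leaf():
            name = nd.taxon.label
            adjacency[name] = []
            return name
        counter[0] += 1
        name = f"{prefix}{counter[0]}"
        adjacency[name] = [walk(ch) for ch in nd.child_nodes()]
        return name

    root = walk(node)
    return adjacency, root


class TestFitch:
    def test_constant_site_zero_changes(self):
        ca = make_ca(["AA", "AA", "AA"], ["LL", "LL"])
        counts = fitch_site_changes(ca)
        assert counts.x1.tolist() == [0, 0]
        assert counts.x2.tolist() == [0, 0]

    def test_two_leaf_difference_is_one_change(self):
        ca = make_ca(["A", "V"], ["L", "L"])
        counts = fitch_site_changes(ca)
        assert counts.x1.tolist() == [1]
        assert counts.x2.tolist() == [0]

    def test_four_leaf_example_matches_bruteforce(self):
        ca = make_ca(["A", "A", "V", "L"], ["K", "K"])
        counts = fitch_site_changes(ca)
        members = {t.taxon for t in ca.tree.leaf_node_iter() if t.taxon.label.startswith("a")}
        sub = ca.tree.mrca(taxa=list(members))
        adjacency, root = tree_to_adjacency(sub)
        states = {"a0": "A", "a1": "A", "a2": "V", "a3": "L"}
        assert counts.x1[0] == fitch_bruteforce(adjacency, root, states)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_random_instances_match_bruteforce(self, seed):
        """Up to 6 leaves per cluster, random residues incl. missing."""
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        alphabet = "AVLK"
        L = 4

        def seqs(n):
            out = []
            for _ in range(n):
                out.append(
                    "".join(
                        "-" if rng.random() < 0.15 else alphabet[rng.integers(4)]
                        for _ in range(L)
                    )
                )
            return out

        s1, s2 = seqs(n1), seqs(n2)
        ca = make_ca(s1, s2)
        counts = fitch_site_changes(ca)
        for k, names, seqlist, got in (
            (1, [f"a{i}" for i in range(n1)], s1, counts.x1),
            (2, [f"b{i}" for i in range(n2)], s2, counts.x2),
        ):
            taxa = [t.taxon for t in ca.tree.leaf_node_iter() if t.taxon.label in names]
            sub = ca.tree.mrca(taxa=taxa)
            adjacency, root = tree_to_adjacency(sub)
            for site in range(L):
                states = {
                    n: (None if s[site] == "-" else s[site])
                    for n, s in zip(names, seqlist)
                }
                assert got[site] == fitch_bruteforce(adjacency, root, states)

    def test_gappy_sites_masked(self):
        ca = make_ca(["A-", "A-", "A-", "AV"], ["KK", "KK"])
        with pytest.warns(UserWarning, match="masked"):
            counts = fitch_site_changes(ca)
        assert counts.included.tolist() == [True, False]


class TestLikelihood:
    def make_counts(self, seed=0, L=50):
        counts, _ = sim.simulate_site_counts(L, 0.3, 1.0, 0.5, seed=seed)
        return counts

    def test_theta_zero_collapses_to_shared_model(self):
        c = self.make_counts()
        lnl = type1_loglik(c, 0.0, 1.2, 0.7)
        expect = _log_p0(c.x1, c.x2, c.d1, c.d2, 1.2, 0.7).sum()
        assert lnl == pytest.approx(float(expect))

    def test_theta_one_collapses_to_independent_model(self):
        c = self.make_counts()
        lnl = type1_loglik(c, 1.0, 1.2, 0.7)
        expect = (_log_p1(c.x1, c.d1, 1.2, 0.7) + _log_p1(c.x2, c.d2, 1.2, 0.7)).sum()
        assert lnl == pytest.approx(float(expect))

    @pytest.mark.parametrize("x,d,a,b", [(0, 1.0, 1.0, 0.5), (3, 0.7, 2.3, 1.1), (7, 1.4, 0.6, 0.2)])
    def test_p1_matches_quadrature(self, x, d, a, b):
        closed = math.exp(float(_log_p1(np.array([x]), d, a, b)[0]))
        assert closed == pytest.approx(negbin_marginal_quadrature(x, d, a, b), rel=1e-8)

    @pytest.mark.parametrize(
        "x1,x2,d1,d2,a,b",
        [(0, 0, 1.0, 1.0, 1.0, 0.5), (2, 5, 0.8, 1.3, 2.0, 1.0), (4, 1, 1.0, 1.0, 0.7, 0.3)],
    )
    def test_p0_matches_quadrature(self, x1, x2, d1, d2, a, b):
        closed = math.exp(
            float(_log_p0(np.array([x1]), np.array([x2]), d1, d2, a, b)[0])
        )
        oracle = shared_rate_marginal_quadrature(x1, x2, d1, d2, a, b)
        assert closed == pytest.approx(oracle, rel=1e-8)

    def test_invalid_parameters_rejected(self):
        c = self.make_counts()
        with pytest.raises(ValueError):
            type1_loglik(c, -0.1, 1.0, 1.0)
        with pytest.raises(ValueError):
            type1_loglik(c, 0.5, -1.0, 1.0)


class TestEstimate:
    def test_alt_fit_never_below_null(self):
        counts, _ = sim.simulate_site_counts(200, 0.3, 1.0, 0.5, seed=1)
        r = estimate_type1(counts)
        assert r.model.lnl >= r.null_model.lnl - 1e-9
        assert r.lrt >= 0.0
        assert 0.0 < r.p <= 1.0

    def test_cluster_relabelling_invariance(self):
        counts, _ = sim.simulate_site_counts(300, 0.4, 1.0, 0.5, seed=2)
        r1 = estimate_type1(counts)
        r2 = estimate_type1(counts.swapped())
        assert r1.model.theta == pytest.approx(r2.model.theta, abs=1e-4)
        assert r1.lrt == pytest.approx(r2.lrt, abs=1e-4)

    def test_divergent_sites_get_higher_posteriors(self):
        counts, _ = sim.simulate_site_counts(300, 0.4, 1.0, 0.5, seed=3)
        r = estimate_type1(counts)
        asym = (counts.x1 >= 4) & (counts.x2 == 0)
        sym = counts.x1 == counts.x2
        if asym.any() and sym.any():
            assert np.nanmin(r.qk[asym]) > np.nanmax(r.qk[sym])

    def test_posteriors_bounded(self):
        counts, _ = sim.simulate_site_counts(200, 0.5, 1.0, 0.5, seed=4)
        r = estimate_type1(counts)
        q = r.qk[counts.included]
        assert ((q >= 0) & (q <= 1)).all()

    def test_recovers_simulated_sites_better_than_chance(self):
        counts, truth = sim.simulate_site_counts(400, 0.3, 0.8, 0.4, seed=5)
        r = estimate_type1(counts)
        hits = set(r.critical_sites_070)
        diverged = set(truth.diverged_sites)
        precision = len(hits & diverged) / max(len(hits), 1)
        assert precision > len(diverged) / 400  # beats random site selection

    def test_all_zero_counts_rejected(self):
        counts = SiteChangeCounts(x1=np.zeros(30, dtype=int), x2=np.zeros(30, dtype=int))
        with pytest.raises(ValueError):
            estimate_type1(counts)


class TestCriticalSites:
    def test_uninformative_posteriors_give_empty_lists(self):
        lo, hi = critical_sites(np.full(5, 0.5))
        assert lo == [] and hi == []

    def test_threshold_example_and_nesting(self):
        lo, hi = critical_sites(np.array([0.71, 0.96, 0.2]))
        assert lo == [1, 2] and hi == [2]
        assert set(hi) <= set(lo)


class TestEndToEnd:
    def test_alignment_pathway_recovers_signal(self):
        """Simulated divergent alignment -> Fitch -> positive theta."""
        ca, counts, truth = sim.simulate_clustered_alignment(
            150, 0.45, 1.0, 0.4, n1=8, n2=8, seed=6
        )
        inferred = fitch_site_changes(ca)
        r = estimate_type1(inferred)
        assert r.model.theta > 0.1
        assert r.p < 0.05
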