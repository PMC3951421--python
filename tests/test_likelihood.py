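import math
from itertools import product

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from dyphylo import (
    CharacterMatrix,
    PhyloTree,
    SubstModel,
    discrete_gamma_rates,
    log_likelihood,
    transition_matrix,
)


def brute_force_loglik(tree, m, model):
    """Sum over all internal-state assignments; independent of pruning."""
    rates = discrete_gamma_rates(model.alpha, model.n_cat)
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    tips = {n.label: n for n in nodes if n.is_leaf}
    pi = [1.0 - model.pi1, model.pi1]
    total = 0.0
    for j in range(m.n_chars):
        site = 0.0
        for r in rates:
            for assign in product([0, 1], repeat=len(internal)):
                st = {id(n): s for n, s in zip(internal, assign)}
                obs_ok = True
                for lbl, n in tips.items():
                    st[id(n)] = int(m.states[m.taxa.index(lbl), j])
                p_sum = 0.0
                # missing tips: sum over their states
                missing_tips = [n for n in tips.values()
                                if st[id(n)] == -1]
                for miss in product([0, 1], repeat=len(missing_tips)):
                    for n, s in zip(missing_tips, miss):
                        st[id(n)] = s
                    p = pi[st[id(tree.root)]]
                    for n in nodes:
                        if n.parent is not None:
                            P = transition_matrix(model, n.length, r)
                            p *= P[st[id(n.parent)], st[id(n)]]
                    p_sum += p
                site += p_sum / model.n_cat
        if model.ascertainment == "variable":
            norm = 0.0
            for const in (0, 1):
                for r in rates:
                    for assign in product([0, 1], repeat=len(internal)):
                        st = {id(n): s for n, s in zip(internal, assign)}
                        for n in tips.values():
                            st[id(n)] = const
                        p = pi[st[id(tree.root)]]
                        for n in nodes:
                            if n.parent is not None:
                                P = transition_matrix(model, n.length, r)
                                p *= P[st[id(n.parent)], st[id(n)]]
                        norm += p / model.n_cat
            site /= 1.0 - norm
        total += math.log(site)
    return total


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        model = SubstModel(pi1=0.3, alpha=1.0)
        assert np.allclose(transition_matrix(model, 0.0), np.eye(2))

    def test_long_time_reaches_stationarity(self):
        model = SubstModel(pi1=0.3, alpha=1.0)
        P = transition_matrix(model, 1e6)
        assert np.allclose(P, [[0.7, 0.3], [0.7, 0.3]])

    @pytest.mark.parametrize("pi1,t,rate", [(0.3, 0.7, 1.0), (0.5, 0.1, 2.5),
                                            (0.85, 2.0, 0.3)])
    def test_matches_matrix_exponential(self, pi1, t, rate):
        model = SubstModel(pi1=pi1, alpha=1.0)
        pi0 = 1 - pi1
        mu = 1.0 / (2 * pi0 * pi1)
        Q = np.array([[-mu * pi1, mu * pi1], [mu * pi0, -mu * pi0]])
        assert np.abs(
            transition_matrix(model, t, rate) - expm(Q * t * rate)
        ).max() <= 1e-12

    def test_rows_sum_to_one(self):
        model = SubstModel(pi1=0.2, alpha=1.0)
        P = transition_matrix(model, 0.37, 1.8)
        assert np.allclose(P.sum(axis=1), 1.0)


class TestDiscreteGamma:
    def test_single_category_is_unit_rate(self):
        assert discrete_gamma_rates(0.7, 1).tolist() == [1.0]

    def test_huge_alpha_collapses_to_one(self):
        rates = discrete_gamma_rates(10000.0, 4)
        assert np.all(np.abs(rates - 1.0) < 0.05)

    @pytest.mark.parametrize("alpha,n_cat", [(0.5, 4), (1.0, 4), (2.3, 6)])
    def test_matches_quadrature_oracle(self, alpha, n_cat):
        # mean of Gamma(alpha, alpha) within each equal-probability bin
        edges = gamma_dist.ppf(
            np.arange(n_cat + 1) / n_cat, alpha, scale=1 / alpha
        )
        expected = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            val, _ = quad(
                lambda x: x * gamma_dist.pdf(x, alpha, scale=1 / alpha),
                lo, hi,
            )
            expected.append(val * n_cat)
        got = discrete_gamma_rates(alpha, n_cat)
        assert np.allclose(got, expected, atol=1e-6)
        assert abs(got.mean() - 1.0) <= 1e-9


class TestLogLikelihood:
    def test_all_missing_single_character_is_zero(self):
        tree = PhyloTree.from_newick("(A:0.1,(B:0.2,C:0.2):0.1);")
        m = CharacterMatrix(
            ("A", "B", "C"), np.full((3, 1), -1, dtype=np.int8)
        )
        model = SubstModel(pi1=0.4, alpha=1.0, ascertainment="none")
        assert log_likelihood(tree, m, model) == pytest.approx(0.0, abs=1e-12)

    def test_two_taxon_closed_form(self):
        # Pr(0, 1) = pi0 * P01(t_a + t_b) by reversibility
        tree = PhyloTree.from_newick("(A:0.3,B:0.4);")
        m = CharacterMatrix(("A", "B"), np.array([[0], [1]], dtype=np.int8))
        model = SubstModel(pi1=0.3, alpha=1.0, n_cat=1, ascertainment="none")
        P = transition_matrix(model, 0.7)
        expected = math.log(0.7 * P[0, 1])
        assert log_likelihood(tree, m, model) == pytest.approx(
            expected, abs=1e-12
        )

    def test_five_taxon_enumeration_oracle(self, five_taxon_tree, rng):
        m = CharacterMatrix(
            ("A", "B", "C", "D", "E"),
            rng.integers(0, 2, size=(5, 3)).astype(np.int8),
        )
        model = SubstModel(pi1=0.4, alpha=0.8, n_cat=4, ascertainment="none")
        assert log_likelihood(five_taxon_tree, m, model) == pytest.approx(
            brute_force_loglik(five_taxon_tree, m, model), abs=1e-10
        )

    def test_ascertainment_matches_enumeration_three_taxa(self, rng):
        tree = PhyloTree.from_newick("(A:0.2,(B:0.3,C:0.1):0.2);")
        m = CharacterMatrix(
            ("A", "B", "C"),
            np.array([[0, 1], [1, 1], [1, 0]], dtype=np.int8),
        )
        model = SubstModel(pi1=0.35, alpha=1.2, n_cat=4,
                           ascertainment="variable")
        assert log_likelihood(tree, m, model) == pytest.approx(
            brute_force_loglik(tree, m, model), abs=1e-10
        )

    def test_missing_data_enumeration(self, five_taxon_tree):
        states = np.array(
            [[0, -1], [1, 0], [-1, 1], [0, 0], [1, -1]], dtype=np.int8
        )
        m = CharacterMatrix(("A", "B", "C", "D", "E"), states)
        model = SubstModel(pi1=0.55, alpha=2.0, n_cat=2, ascertainment="none")
        assert log_likelihood(five_taxon_tree, m, model) == pytest.approx(
            brute_force_loglik(five_taxon_tree, m, model), abs=1e-10
        )

    def test_rerooting_invariance(self, five_taxon_tree, rng):
        import dendropy

        m = CharacterMatrix(
            ("A", "B", "C", "D", "E"),
            rng.integers(0, 2, size=(5, 6)).astype(np.int8),
        )
        model = SubstModel(pi1=0.3, alpha=1.0, ascertainment="none")
        base = log_likelihood(five_taxon_tree, m, model)
        dtree = five_taxon_tree.to_dendropy()
        for edge in list(dtree.preorder_edge_iter())[3:6]:
            if edge.head_node is dtree.seed_node:
                continue
            dt = dtree.clone(depth=1)
            # find matching edge in the clone by split
            dt.encode_bipartitions()
            dtree.encode_bipartitions()
            target = None
            for e in dt.preorder_edge_iter():
                if (e.bipartition is not None and edge.bipartition is not None
                        and e.bipartition == edge.bipartition):
                    target = e
                    break
            if target is None or target.length is None:
                continue
            dt.reroot_at_edge(target, length1=target.length / 2,
                              length2=target.length / 2)
            rerooted = PhyloTree._from_dendropy(dt)
            assert log_likelihood(rerooted, m, model) == pytest.approx(
                base, abs=1e-9
            )

    def test_all_missing_taxon_on_zero_branch_is_neutral(self, rng):
        m3 = CharacterMatrix(
            ("A", "B", "C"), rng.integers(0, 2, size=(3, 5)).astype(np.int8)
        )
        model = SubstModel(pi1=0.4, alpha=1.0, ascertainment="none")
        t3 = PhyloTree.from_newick("(A:0.2,(B:0.3,C:0.1):0.15);")
        base = log_likelihood(t3, m3, model)
        t4 = PhyloTree.from_newick("((A:0.2,X:0.0):0.0,(B:0.3,C:0.1):0.15);")
        m4 = CharacterMatrix(
            ("A", "B", "C", "X"),
            np.vstack([m3.states, np.full((1, 5), -1, dtype=np.int8)]),
        )
        assert log_likelihood(t4, m4, model) == pytest.approx(base, abs=1e-12)

    def test_taxon_mismatch_reports_difference(self, five_taxon_tree):
        m = CharacterMatrix(("A", "B"), np.zeros((2, 1), dtype=np.int8))
        with pytest.raises(ValueError, match="differ"):
            log_likelihood(five_taxon_tree, m,
                           SubstModel(pi1=0.5, alpha=1.0))


def test_binary_fast_path_matches_generic(rng):
    """The compiled binary-tree kernel and the generic pruning path agree."""
    from dyphylo.likelihood import (
        prune_site_likelihoods,
        prune_site_likelihoods_binary,
    )

    n = 6
    # random binary tree encoded as arrays: tips 0..5, internals 6..10
    left = np.full(2 * n - 1, -1)
    right = np.full(2 * n - 1, -1)
    avail = list(range(n))
    for v in range(n, 2 * n - 1):
        i = int(rng.integers(len(avail)))
        a = avail.pop(i)
        j = int(rng.integers(len(avail)))
        b = avail.pop(j)
        left[v], right[v] = a, b
        avail.append(v)
    blens = rng.uniform(0.05, 0.5, size=2 * n - 1)
    tipdata = rng.integers(0, 2, size=(n, 7)).astype(np.int8)
    tipdata[rng.random(tipdata.shape) < 0.2] = -1
    tip_row = np.concatenate([np.arange(n), np.full(n - 1, -1)])
    rates = discrete_gamma_rates(0.8, 4)
    order_internal = np.arange(n, 2 * n - 1)
    fast = prune_site_likelihoods_binary(
        order_internal, left, right, blens, tip_row, tipdata, 0.35, rates
    )
    children = [[] for _ in range(2 * n - 1)]
    for v in range(n, 2 * n - 1):
        children[v] = [int(left[v]), int(right[v])]
    slow = prune_site_likelihoods(
        list(range(2 * n - 1)), children, blens, tip_row, tipdata, 0.35, rates
    )
    assert np.allclose(fast, slow, rtol=0, atol=1e-14)
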