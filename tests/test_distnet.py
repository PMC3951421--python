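import itertools

import networkx as nx
import numpy as np
import pytest

from dyphylo import (
    CharacterMatrix,
    DistanceMatrix,
    delta_scores,
    distance_matrix,
    neighbor_net,
    q_residuals,
    splits_to_graph,
    treelikeness,
)
from dyphylo.distnet import fit_split_weights, neighbor_net_ordering
from dyphylo.synth import simulate_clock_tree

from conftest import tree_distance_matrix


class TestDistanceMatrix:
    def test_identical_rows_give_zero(self):
        m = CharacterMatrix(
            ("A", "B"), np.array([[0, 1, 1], [0, 1, 1]], dtype=np.int8)
        )
        assert distance_matrix(m).d[0, 1] == 0.0

    def test_pairwise_deletion(self):
        # 0101 vs 0?11 -> one mismatch over three comparable characters
        m = CharacterMatrix(
            ("A", "B"),
            np.array([[0, 1, 0, 1], [0, -1, 1, 1]], dtype=np.int8),
        )
        dm = distance_matrix(m)
        assert dm.d[0, 1] == pytest.approx(1 / 3)
        assert dm.n_comparable[0, 1] == 3

    def test_complementary_rows_give_one(self):
        m = CharacterMatrix(
            ("A", "B"), np.array([[0, 1, 0], [1, 0, 1]], dtype=np.int8)
        )
        assert distance_matrix(m).d[0, 1] == 1.0

    def test_no_comparable_characters_names_pair(self):
        m = CharacterMatrix(
            ("A", "B"), np.array([[0, -1], [-1, 1]], dtype=np.int8)
        )
        with pytest.raises(ValueError, match="'A' and 'B'"):
            distance_matrix(m)


class TestDeltaScores:
    def test_additive_distances_score_zero(self, additive_distances):
        assert delta_scores(additive_distances).avg_delta == 0.0

    def test_box_scores_one(self, box_distances):
        assert delta_scores(box_distances).avg_delta == 1.0

    def test_fewer_than_four_taxa_rejected(self):
        dm = DistanceMatrix(("A", "B", "C"), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            delta_scores(dm)

    def test_relabeling_and_rescaling_invariance(self, rng):
        n = 6
        d = rng.uniform(0.1, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        taxa = tuple("ABCDEF")
        base = delta_scores(DistanceMatrix(taxa, d))
        perm = rng.permutation(n)
        relabeled = delta_scores(
            DistanceMatrix(
                tuple(taxa[i] for i in perm), d[np.ix_(perm, perm)]
            )
        )
        assert relabeled.avg_delta == pytest.approx(base.avg_delta, abs=1e-12)
        for t in taxa:
            assert relabeled.per_taxon_delta[t] == pytest.approx(
                base.per_taxon_delta[t], abs=1e-12
            )
        scaled = delta_scores(DistanceMatrix(taxa, 7.3 * d))
        assert scaled.avg_delta == pytest.approx(base.avg_delta, abs=1e-12)

    def test_per_taxon_consistency_with_quartet_average(self, rng):
        # avg over quartets == weighted recombination of per-taxon means
        n = 7
        d = rng.uniform(0.1, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(tuple(f"t{i}" for i in range(n)), d)
        rep = delta_scores(dm)
        # each quartet contributes to exactly 4 taxa; per-taxon means use
        # C(n-1,3) quartets each
        per_taxon_total = sum(rep.per_taxon_delta.values())
        n_quart = len(list(itertools.combinations(range(n), 4)))
        per_taxon_quarts = len(list(itertools.combinations(range(n - 1), 3)))
        assert per_taxon_total * per_taxon_quarts / 4 == pytest.approx(
            rep.avg_delta * n_quart, abs=1e-9
        )


class TestQResiduals:
    def test_additive_distances_score_zero(self, additive_distances):
        assert q_residuals(additive_distances).avg_q_residual == 0.0

    def test_box_hand_evaluation(self, box_distances):
        # mean off-diagonal 8/6 -> scale 3/4; sums 3.0, 1.5, 1.5 -> (1.5)^2
        assert q_residuals(box_distances).avg_q_residual == pytest.approx(2.25)

    def test_all_zero_matrix_rejected(self):
        dm = DistanceMatrix(tuple("ABCD"), np.zeros((4, 4)))
        with pytest.raises(ValueError, match="rescaling"):
            q_residuals(dm)


class TestNeighborNet:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        s = neighbor_net(DistanceMatrix(("A", "B", "C"), d))
        w = {frozenset(side): wt for side, wt in zip(s.splits, s.weights)}
        assert w[frozenset({"B", "C"})] == pytest.approx(0.1)  # = side of A
        assert w[frozenset({"B"})] == pytest.approx(0.3)
        assert w[frozenset({"C"})] == pytest.approx(0.5)

    def test_four_taxon_additive_recovers_tree_splits(self, additive_distances):
        s = neighbor_net(additive_distances)
        got = {frozenset(side): wt for side, wt in zip(s.splits, s.weights)}
        expected = {
            frozenset({"B"}): 1.0,
            frozenset({"C"}): 1.0,
            frozenset({"D"}): 1.0,
            frozenset({"B", "C", "D"}): 1.0,  # trivial split of A
            frozenset({"C", "D"}): 1.0,
        }
        assert set(got) == set(expected)
        for k in expected:
            assert got[k] == pytest.approx(expected[k], abs=1e-8)

    @pytest.mark.parametrize("n_taxa,seed", [(6, 0), (7, 1), (8, 2), (8, 5)])
    def test_recovers_random_tree_splits_exactly(self, n_taxa, seed):
        tree = simulate_clock_tree(n_taxa, 1.0, seed=seed)
        dm = tree_distance_matrix(tree)
        s = neighbor_net(dm)
        tree_splits = set()
        full = frozenset(dm.taxa)
        for clade in tree.clades():
            if 0 < len(clade) < n_taxa:
                side = clade if dm.taxa[0] not in clade else full - clade
                tree_splits.add(side)
        assert set(s.splits) == tree_splits
        induced = s.induced_distances()
        assert np.allclose(induced.d, dm.d, atol=1e-7)

    def test_five_taxon_fit_beats_exhaustive_orderings(self, rng):
        # residual of the fitted system is no worse than the best over all
        # distinct circular orderings, each fitted exhaustively
        n = 5
        d = rng.uniform(0.2, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(tuple(f"t{i}" for i in range(n)), d)
        s = neighbor_net(dm)
        my_resid = np.sqrt(
            ((s.induced_distances().d - dm.d)[np.triu_indices(n, 1)] ** 2).sum()
        )
        best = np.inf
        from dyphylo.distnet import _interval_splits

        for perm in itertools.permutations(dm.taxa[1:]):
            order = (dm.taxa[0],) + perm
            cands = _interval_splits(order)
            _, resid = fit_split_weights(dm, cands)
            best = min(best, resid)
        assert my_resid <= best + 1e-6

    def test_nnls_residual_monotone_under_split_addition(self, rng):
        n = 5
        d = rng.uniform(0.2, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(tuple(f"t{i}" for i in range(n)), d)
        order = neighbor_net_ordering(dm)
        from dyphylo.distnet import _interval_splits

        cands = _interval_splits(order)
        prev = np.inf
        for k in range(1, len(cands) + 1):
            _, resid = fit_split_weights(dm, cands[:k])
            assert resid <= prev + 1e-10
            prev = resid

    def test_ordering_matches_phangorn_reference(self, tmp_path, rng):
        # independent implementation check on tie-free random distances
        n = 7
        d = rng.uniform(0.2, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(tuple(f"t{i + 1}" for i in range(n)), d)
        ours = list(neighbor_net_ordering(dm))
        import subprocess

        np.savetxt(tmp_path / "d.csv", d, delimiter=",")
        script = tmp_path / "nn.R"
        script.write_text(
            'suppressMessages(library(phangorn))\n'
            f'd <- as.matrix(read.csv("{tmp_path}/d.csv", header=FALSE))\n'
            'rownames(d) <- colnames(d) <- paste0("t", seq_len(nrow(d)))\n'
            'ord <- phangorn:::getOrderingNN(as.dist(d))\n'
            'cat(ord, sep=",")\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True,
            timeout=300,
        )
        assert out.returncode == 0, out.stderr
        ref = [f"t{int(i)}" for i in out.stdout.strip().split(",")]
        # circular orderings are equivalent up to rotation and reflection
        def canon(seq):
            best = None
            for s in (seq, seq[::-1]):
                for r in range(len(s)):
                    rot = tuple(s[r:] + s[:r])
                    if best is None or rot < best:
                        best = rot
            return best

        assert canon(ours) == canon(ref)


class TestSplitsGraph:
    def test_tree_compatible_system_gives_tree(self, additive_distances):
        g = splits_to_graph(neighbor_net(additive_distances))
        assert nx.is_tree(g)
        splits_used = {d["split"] for _, _, d in g.edges(data=True)}
        assert len(splits_used) == 5

    def test_box_gives_four_cycle(self, box_distances):
        g = splits_to_graph(neighbor_net(box_distances))
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 4
        assert len(nx.cycle_basis(g)) == 1

    def test_nontreelike_data_has_cycles(self, rng):
        # borrowing-free signal plus conflicting noise yields avg_delta > 0
        # and hence at least one box in the splits graph
        states = rng.integers(0, 2, size=(8, 60)).astype(np.int8)
        m = CharacterMatrix(tuple(f"t{i}" for i in range(8)), states)
        dm = distance_matrix(m)
        rep = treelikeness(dm)
        assert rep.avg_delta > 0
        g = splits_to_graph(neighbor_net(dm))
        assert len(nx.cycle_basis(g)) >= 1

    def test_taxon_faces_separated_by_their_splits(self, box_distances):
        s = neighbor_net(box_distances)
        g = splits_to_graph(s)
        tn = g.graph["taxon_node"]
        # for each split, the minimal cut between taxa on opposite sides
        # must use an edge of that split class
        for si, side in enumerate(s.splits):
            a = next(iter(side))
            b = next(t for t in s.taxa if t not in side)
            path = nx.shortest_path(g, tn[a], tn[b])
            crossed = {
                g.edges[u, v]["split"] for u, v in zip(path, path[1:])
            }
            assert si in crossed
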