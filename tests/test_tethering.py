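"""Tethering-potential scoring, ranking and tie randomization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenotether.net_io import AnnotationSet, PhenotypeScheme, WeightedNetwork, seed_set
from phenotether.tethering import (
    ScoreVector,
    interaction_weights,
    predict_unlabeled,
    rank_prediction,
    tethering_potential,
    top_category,
)
from phenotether.yeast import ybr039w_neighborhood, ydl028c_neighborhood

from conftest import brute_force_potential, random_instance


def neighborhood_seeds(ex):
    return [p for p in seed_set(ex.annotations, ex.network) if p != ex.query]


class TestInteractionWeights:
    def test_published_atp_synthase_weights(self):
        """The confidence vector to YBR039W's eight seed neighbors."""
        ex = ybr039w_neighborhood()
        w = interaction_weights(ex.network, ex.query, neighborhood_seeds(ex))
        assert w.tolist() == [999, 999, 999, 917, 934, 999, 997, 986]

    def test_self_position_is_zero(self):
        net = WeightedNetwork.from_edges([("A", "B", 900)])
        assert interaction_weights(net, "A", ["A", "B"]).tolist() == [0, 900]

    def test_isolated_and_absent_queries_give_zero_vectors(self):
        net = WeightedNetwork.from_edges([("A", "B", 900)])
        assert interaction_weights(net, "Z", ["A", "B"]).tolist() == [0, 0]

    def test_empty_seed_list_rejected(self):
        net = WeightedNetwork.from_edges([("A", "B", 900)])
        with pytest.raises(ValueError):
            interaction_weights(net, "A", [])


class TestTetheringPotential:
    def test_atp_synthase_neighborhood_sums(self):
        """Summed confidences per phenotype around YBR039W: the auxotrophy
        category collects all eight neighbors, morphology two, conditional one."""
        ex = ybr039w_neighborhood()
        sv = tethering_potential(
            ex.network, ex.query, ex.annotations, neighborhood_seeds(ex), ex.scheme
        )
        expected = np.zeros(11, dtype=int)
        expected[4 - 1] = 7830
        expected[5 - 1] = 1920
        expected[1 - 1] = 986
        assert sv.scores.tolist() == expected.tolist()

    def test_cell_cycle_neighborhood_sums(self):
        ex = ydl028c_neighborhood()
        sv = tethering_potential(
            ex.network, ex.query, ex.annotations, neighborhood_seeds(ex), ex.scheme
        )
        by_cat = dict(zip(range(1, 12), sv.scores.tolist()))
        assert by_cat[2] == 9736
        assert by_cat[5] == 3970
        assert by_cat[1] == 2891
        assert by_cat[8] == 929
        assert sum(by_cat.values()) == 9736 + 3970 + 2891 + 929

    def test_empty_seed_set_gives_all_zero(self, path_graph):
        net, ann, scheme = path_graph
        sv = tethering_potential(net, "A", ann, [], scheme)
        assert sv.all_zero

    def test_query_in_seed_set_does_not_vote_for_itself(self, path_graph):
        net, ann, scheme = path_graph
        with_self = tethering_potential(net, "B", ann, ["A", "B", "C"], scheme)
        without = tethering_potential(net, "B", ann, ["A", "C"], scheme)
        assert with_self.scores.tolist() == without.scores.tolist()

    def test_unannotated_seed_rejected(self, path_graph):
        net, ann, scheme = path_graph
        with pytest.raises(ValueError, match="without annotation"):
            tethering_potential(net, "A", ann, ["A", "Z"], scheme)

    @settings(max_examples=150, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        """Package scoring equals the naive sum over all seed pairs."""
        rng = np.random.default_rng(seed)
        net, ann, scheme, edge_weights, labels, names = random_instance(rng)
        query = names[int(rng.integers(len(names)))]
        n_seeds = int(rng.integers(1, len(names) + 1))
        seeds = list(rng.choice(names, size=n_seeds, replace=False))
        sv = tethering_potential(net, query, ann, seeds, scheme)
        assert sv.scores.tolist() == brute_force_potential(
            edge_weights, labels, query, seeds, scheme.K
        )

    def test_conservation_of_total_score(self):
        """Sum of F_j equals sum over neighbors of weight times label count."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            net, ann, scheme, edge_weights, labels, names = random_instance(rng)
            query = names[0]
            seeds = names[1:]
            sv = tethering_potential(net, query, ann, seeds, scheme)
            total = sum(
                edge_weights.get(frozenset((query, s)), 0) * len(labels[s])
                for s in seeds
            )
            assert int(sv.scores.sum()) == total

    def test_adding_edge_monotone_in_its_category_only(self, path_graph):
        net, ann, scheme = path_graph
        before = tethering_potential(net, "A", ann, ["B", "C"], scheme).scores
        net.add_edge("A", "C", 700)  # C carries category 1 only
        after = tethering_potential(net, "A", ann, ["B", "C"], scheme).scores
        assert after[0] > before[0]
        assert after[1:].tolist() == before[1:].tolist()

    def test_permutation_equivariance(self, scheme3):
        """Relabeling the categories permutes the score vector identically."""
        net = WeightedNetwork.from_edges([("Q", "A", 10), ("Q", "B", 20), ("Q", "C", 30)])
        labels = {"A": {1}, "B": {2, 3}, "C": {3}, "Q": {1}}
        perm = {1: 3, 2: 1, 3: 2}
        relabeled = {p: {perm[c] for c in cats} for p, cats in labels.items()}
        sv = tethering_potential(net, "Q", AnnotationSet(labels, scheme3),
                                 ["A", "B", "C"], scheme3)
        sv_p = tethering_potential(net, "Q", AnnotationSet(relabeled, scheme3),
                                   ["A", "B", "C"], scheme3)
        for c in (1, 2, 3):
            assert sv.scores[c - 1] == sv_p.scores[perm[c] - 1]


class TestRanking:
    def test_cell_cycle_ranking_order(self):
        """Nonzero categories sort 9736 > 3970 > 2891 > 929; the paper-stated
        top-2 candidates are cell cycle defects then morphology mutants."""
        ex = ydl028c_neighborhood()
        sv = tethering_potential(
            ex.network, ex.query, ex.annotations, neighborhood_seeds(ex), ex.scheme
        )
        rp = rank_prediction(sv, rng=0)
        assert rp.order[:4] == (2, 5, 1, 8)
        assert ex.scheme.label(rp.order[0]) == "Cell cycle defects"
        assert ex.scheme.label(rp.order[1]) == "Cell morphology and organelle mutants"
        assert set(rp.order[4:]) == {3, 4, 6, 7, 9, 10, 11}
        assert not rp.all_zero

    def test_order_is_permutation_and_scores_non_increasing(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            K = int(rng.integers(2, 8))
            sv = ScoreVector("Q", rng.integers(0, 5, size=K))
            rp = rank_prediction(sv, rng)
            assert sorted(rp.order) == list(range(1, K + 1))
            assert all(
                rp.sorted_scores[i] >= rp.sorted_scores[i + 1] for i in range(K - 1)
            )
            for group in rp.tie_groups:
                vals = {rp.sorted_scores[r - 1] for r in group}
                assert len(vals) == 1

    def test_no_ties_means_rng_independent(self):
        sv = ScoreVector("Q", np.array([5, 1, 9, 3]))
        orders = {rank_prediction(sv, rng=s).order for s in range(10)}
        assert orders == {(3, 1, 4, 2)}

    def test_all_zero_is_one_tie_group_and_reproducible(self):
        sv = ScoreVector("Q", np.zeros(5, dtype=int))
        rp1 = rank_prediction(sv, rng=42)
        rp2 = rank_prediction(sv, rng=42)
        assert rp1.all_zero
        assert rp1.tie_groups == ((1, 2, 3, 4, 5),)
        assert rp1.order == rp2.order

    def test_max_tie_randomized_uniformly(self):
        """Two categories tied at the maximum each rank first ~50% of draws."""
        sv = ScoreVector("Q", np.array([7, 7, 1, 0]))
        rng = np.random.default_rng(123)
        first = sum(rank_prediction(sv, rng).order[0] == 1 for _ in range(10_000))
        assert abs(first / 10_000 - 0.5) < 0.02

    def test_top_category(self):
        assert top_category(ScoreVector("Q", np.array([5, 0, 0]))) == 1
        assert top_category(ScoreVector("Q", np.zeros(3))) is None
        tied = ScoreVector("Q", np.array([4, 4, 0]))
        tops = {top_category(tied, rng=s) for s in range(20)}
        assert tops == {1, 2}


class TestPredictUnlabeled:
    def test_only_unannotated_nodes_predicted(self, scheme3):
        net = WeightedNetwork.from_edges([("A", "U", 900), ("A", "B", 950)])
        ann = AnnotationSet({"A": {3}, "B": {1}}, scheme3)
        preds = predict_unlabeled(net, ann, scheme3, rng=0)
        assert set(preds) == {"U"}
        assert preds["U"].order[0] == 3  # single voter of category 3

    def test_fully_annotated_network_gives_empty_map(self, path_graph):
        net, ann, scheme = path_graph
        assert predict_unlabeled(net, ann, scheme, rng=0) == {}
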