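"""Distance matrices, density thresholding, affinity propagation, rich clubs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import AffinityPropagation
from sklearn.metrics import adjusted_rand_score

from chemtrans.network import (DistanceMatrix, affinity_propagation,
                               build_rich_clubs, density_edge_count,
                               detect_communities, giant_component,
                               glob_to_distance, threshold_by_density)
from oracles import giant_component_oracle


def _block_distances(n_classes, per_class, within, between, seed=0, noise=0.02):
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_classes), per_class)
    n = len(labels)
    d = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    eps = np.triu(rng.normal(0, noise, (n, n)), 1)
    d = np.clip(d + eps + eps.T, 0, 1)
    np.fill_diagonal(d, 0.0)
    ids = tuple(f"c{i:02d}" for i in range(n))
    return DistanceMatrix(ids, d), labels


class TestDistanceMatrix:
    def test_validation(self):
        ids = ("a", "b")
        with pytest.raises(ValueError, match="shape"):
            DistanceMatrix(ids, np.zeros((3, 3)))
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(ids, np.array([[0.0, 1.0], [0.5, 0.0]]))
        with pytest.raises(ValueError, match="missing"):
            DistanceMatrix(ids, np.array([[0.0, np.nan], [np.nan, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(ids, np.array([[1.0, 0.5], [0.5, 0.0]]))
        with pytest.raises(ValueError, match="nonnegative"):
            DistanceMatrix(ids, np.array([[0.0, -0.5], [-0.5, 0.0]]))

    def test_frame_roundtrip(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 0.4], [0.4, 0.0]]))
        back = DistanceMatrix.from_frame(dm.to_frame())
        assert back.ids == dm.ids
        assert np.allclose(back.values, dm.values)

    def test_frame_with_mismatched_labels_rejected(self):
        df = pd.DataFrame(np.zeros((2, 2)), index=["a", "b"], columns=["a", "c"])
        with pytest.raises(ValueError, match="identifiers differ"):
            DistanceMatrix.from_frame(df)


class TestGlobToDistance:
    def test_extremes(self):
        s = np.array([[3.0, 3.0], [3.0, 3.0]])
        assert np.allclose(glob_to_distance(s, ids=("a", "b")).values,
                           [[0.0, 0.0], [0.0, 0.0]])
        s = np.array([[3.0, 0.0], [0.0, 3.0]])
        assert np.allclose(glob_to_distance(s, ids=("a", "b")).values,
                           [[0.0, 1.0], [1.0, 0.0]])

    def test_midpoint(self):
        s = np.array([[3.0, 1.5], [1.5, 3.0]])
        dm = glob_to_distance(s, ids=("a", "b"))
        assert dm.values[0, 1] == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 3\]"):
            glob_to_distance(np.array([[3.0, 3.5], [3.5, 3.0]]), ids=("a", "b"))


class TestDensityEdgeCount:
    def test_small_example(self):
        # 5 nodes -> 10 pairs; 20% density keeps floor(2.0) = 2 edges
        assert density_edge_count(5, 0.2) == 2

    def test_cmap_scale(self):
        assert density_edge_count(5452, 0.05) == 742971

    def test_total_pairs(self):
        assert density_edge_count(5452, 1.0) == 14859426
        assert density_edge_count(1309, 1.0) == 856086

    def test_invalid_density(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="density"):
                density_edge_count(10, bad)


class TestThresholdByDensity:
    def test_keeps_k_closest_pairs(self):
        d = np.array([
            [0.0, 0.1, 0.5, 0.9],
            [0.1, 0.0, 0.2, 0.8],
            [0.5, 0.2, 0.0, 0.7],
            [0.9, 0.8, 0.7, 0.0],
        ])
        dm = DistanceMatrix(("a", "b", "c", "d"), d)
        net = threshold_by_density(dm, 0.34)  # floor(0.34 * 6) = 2 edges
        assert len(net.edges) == 2
        assert set(map(tuple, net.edges[["drug_a", "drug_b"]].values)) == {
            ("a", "b"), ("b", "c")}
        assert net.threshold_distance == pytest.approx(0.2)

    def test_ties_at_cutoff_included_with_warning(self):
        d = np.array([
            [0.0, 0.1, 0.1, 0.9],
            [0.1, 0.0, 0.1, 0.9],
            [0.1, 0.1, 0.0, 0.9],
            [0.9, 0.9, 0.9, 0.0],
        ])
        dm = DistanceMatrix(("a", "b", "c", "d"), d)
        with pytest.warns(UserWarning, match="tied"):
            net = threshold_by_density(dm, 0.34)
        assert len(net.edges) == 3  # all three pairs tied at 0.1

    def test_zero_edges_when_density_too_small(self):
        dm, _ = _block_distances(1, 3, 0.2, 0.8)
        net = threshold_by_density(dm, 0.1)  # floor(0.3) = 0
        assert net.edges.empty

    def test_single_compound_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            threshold_by_density(DistanceMatrix(("a",), np.zeros((1, 1))), 0.5)


class TestGiantComponent:
    def test_two_components(self):
        d = np.full((5, 5), 0.9)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.1
        d[3, 4] = d[4, 3] = 0.1
        dm = DistanceMatrix(tuple("abcde"), d)
        net = threshold_by_density(dm, 0.3)  # 3 edges
        assert giant_component(net) == (3, 2)

    def test_matches_union_find_oracle(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 20
            raw = rng.uniform(0.05, 1.0, (n, n))
            d = np.triu(raw, 1)
            d = d + d.T
            dm = DistanceMatrix(tuple(f"n{i}" for i in range(n)), d)
            net = threshold_by_density(dm, 0.1)
            edges = list(map(tuple, net.edges[["drug_a", "drug_b"]].values))
            assert giant_component(net) in giant_component_oracle(dm.ids, edges)

    def test_empty_network(self):
        dm, _ = _block_distances(1, 3, 0.2, 0.8)
        net = threshold_by_density(dm, 0.1)
        assert giant_component(net) == (0, 0)
        assert giant_component_oracle(dm.ids, []) == {(0, 0)}


class TestAffinityPropagation:
    def test_two_clear_blocks(self):
        dm, labels = _block_distances(2, 6, 0.1, 0.9, seed=1)
        got, exemplars, converged = affinity_propagation(-dm.values)
        assert converged
        assert adjusted_rand_score(labels, got) == pytest.approx(1.0)
        assert len(exemplars) == 2

    def test_matches_sklearn_reference(self):
        # independent reference implementation on the same similarities
        for seed in (0, 1, 2):
            dm, labels = _block_distances(4, 6, 0.15, 0.85, seed=seed)
            s = -dm.values
            ours, _, _ = affinity_propagation(s)
            ref = AffinityPropagation(affinity="precomputed", damping=0.9,
                                      max_iter=1000, convergence_iter=50,
                                      random_state=0).fit(s)
            assert adjusted_rand_score(ref.labels_, ours) >= 0.9
            assert adjusted_rand_score(labels, ours) >= 0.9

    def test_single_item(self):
        labels, exemplars, converged = affinity_propagation(np.zeros((1, 1)))
        assert labels.tolist() == [0] and exemplars.tolist() == [0] and converged

    def test_invalid_damping(self):
        with pytest.raises(ValueError, match="damping"):
            affinity_propagation(np.zeros((3, 3)), damping=0.3)

    def test_exemplars_label_themselves(self):
        dm, _ = _block_distances(3, 5, 0.2, 0.8, seed=3)
        labels, exemplars, _ = affinity_propagation(-dm.values)
        for e in exemplars:
            assert labels[e] == e


class TestCommunities:
    def test_planted_classes_recovered(self):
        dm, labels = _block_distances(3, 6, 0.2, 0.8, seed=5)
        comms = detect_communities(dm)
        assigned = {}
        for c in comms:
            for m in c.members:
                assigned[m] = c.id
        got = [assigned[i] for i in dm.ids]
        assert adjusted_rand_score(labels, got) == pytest.approx(1.0)

    def test_reportable_is_strictly_greater(self):
        dm, _ = _block_distances(4, 3, 0.2, 0.8, seed=7)
        comms = detect_communities(dm, min_size=3)
        for c in comms:
            assert c.reportable == (len(c.members) > 3)
        assert all(len(c.members) == 3 for c in comms)
        assert not any(c.reportable for c in comms)

    def test_exemplar_is_a_member(self):
        dm, _ = _block_distances(3, 5, 0.2, 0.8, seed=9)
        for c in detect_communities(dm):
            assert c.exemplar in c.members


class TestRichClubs:
    def test_partition_of_communities(self):
        dm, _ = _block_distances(4, 5, 0.2, 0.8, seed=11)
        comms = detect_communities(dm)
        clubs = build_rich_clubs(comms, dm)
        covered = sorted(cid for rc in clubs for cid in rc.community_ids)
        assert covered == sorted(c.id for c in comms)
        for rc in clubs:
            assert rc.exemplar_community in rc.community_ids

    def test_single_community(self):
        dm, _ = _block_distances(1, 4, 0.2, 0.8, seed=13)
        comms = detect_communities(dm)
        if len(comms) == 1:
            clubs = build_rich_clubs(comms, dm)
            assert len(clubs) == 1
            assert clubs[0].community_ids == frozenset({comms[0].id})

    def test_no_communities_rejected(self):
        dm, _ = _block_distances(1, 3, 0.2, 0.8)
        with pytest.raises(ValueError, match="no communities"):
            build_rich_clubs([], dm)
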