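"""Tracing SVM weights back to clusters, edges, regions, and networks."""

import numpy as np
import pandas as pd
import pytest

from efcpipe import (
    EdgeClustering,
    StructuralError,
    cluster_weights,
    connection_contributions,
    edge_pairs,
    network_indices,
    num_edges,
    region_contributions,
    top_fraction_edges,
)
from efcpipe.classify import TrainedFold


def make_fold(rep, fold, key, selected, weights, clustering=None):
    selected = np.asarray(selected)
    weights = np.asarray(weights, dtype=float)
    return TrainedFold(
        rep, fold, key, selected, weights, 0.0, np.array([0]), ("s1",),
        np.array([0.5]), np.array([1]), clustering,
    )


class TestClusterWeights:
    def test_always_selected_cluster(self):
        folds = [
            make_fold(r, f, (20, 8), [2], [0.5]) for r in range(2) for f in range(2)
        ]
        (rec,) = cluster_weights(folds)
        assert rec.appearances == 4
        assert rec.occurrence_rate == 1.0
        assert rec.normalized_weight == pytest.approx(0.5)

    def test_partially_selected_cluster(self):
        folds = [make_fold(0, 0, (20, 8), [1], [0.8])]
        folds += [make_fold(r, f, (20, 8), [], []) for (r, f) in [(0, 1), (1, 0), (1, 1)]]
        (rec,) = cluster_weights(folds)
        assert rec.occurrence_rate == pytest.approx(0.25)
        assert rec.normalized_weight == pytest.approx(0.2)

    def test_never_selected_absent(self):
        folds = [make_fold(r, f, (20, 8), [0], [1.0]) for r in range(2) for f in range(2)]
        records = cluster_weights(folds)
        assert {r.cluster for r in records} == {0}

    def test_incomplete_folds_rejected(self):
        folds = [make_fold(0, 0, (20, 8), [0], [1.0]), make_fold(1, 1, (20, 8), [0], [1.0])]
        with pytest.raises(StructuralError, match="incomplete"):
            cluster_weights(folds)


def clustering_of(assignment):
    assignment = np.asarray(assignment)
    return EdgeClustering(assignment, assignment.max() + 1, assignment.max() + 1, 0)


class TestConnectionContributions:
    def test_members_inherit_full_weight(self):
        folds = [make_fold(r, f, (20, 8), [0], [0.6]) for r in range(1) for f in range(1)]
        records = cluster_weights(folds, n_fits=1)
        cl = clustering_of([0, 0, 0, 1, 1])
        contrib = connection_contributions(records, {(20, 8): cl}, E=5)
        np.testing.assert_allclose(contrib, [0.6, 0.6, 0.6, 0.0, 0.0])

    def test_contributions_add_across_configurations(self):
        folds = [
            make_fold(0, 0, (20, 8), [0], [0.4]),
            make_fold(0, 1, (30, 8), [1], [0.6]),
        ]
        records = cluster_weights(folds, n_fits=2)
        cls = {
            (20, 8): clustering_of([0, 0, 1, 1]),
            (30, 8): clustering_of([1, 0, 0, 1]),
        }
        contrib = connection_contributions(records, cls, E=4)
        # edge 0: |0.4*0.5| from config A cluster 0 + |0.6*0.5| from config B cluster 1
        assert contrib[0] == pytest.approx(0.2 + 0.3)

    def test_matches_double_loop_oracle(self, rng):
        E, K = 30, 4
        assignment = rng.integers(0, K, size=E)
        assignment[:K] = np.arange(K)
        cl = clustering_of(assignment)
        folds = []
        for r in range(2):
            for f in range(3):
                sel = rng.choice(K, size=2, replace=False)
                folds.append(make_fold(r, f, (20, 8), sel, rng.standard_normal(2)))
        records = cluster_weights(folds)
        got = connection_contributions(records, {(20, 8): cl}, E)
        expected = np.zeros(E)
        for rec in records:  # explicit (record, member edge) double loop
            for e in range(E):
                if assignment[e] == rec.cluster:
                    expected[e] += abs(rec.normalized_weight)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_size_normalized_mode(self):
        folds = [make_fold(0, 0, (20, 8), [0], [0.9])]
        records = cluster_weights(folds, n_fits=1)
        cl = clustering_of([0, 0, 0, 1])
        contrib = connection_contributions(records, {(20, 8): cl}, 4, size_normalized=True)
        np.testing.assert_allclose(contrib, [0.3, 0.3, 0.3, 0.0])


class TestRegionContributions:
    def test_star_hub_sums_spokes(self):
        R = 5
        contrib = np.zeros(num_edges(R))
        iu, ju = edge_pairs(R)
        for eid in range(len(iu)):  # edges incident to ROI 0 get weight
            if iu[eid] == 0:
                contrib[eid] = 0.25
        roi = region_contributions(contrib, R)
        assert roi[0] == pytest.approx(0.25 * 4)

    def test_handshake_identity(self, rng):
        R = 8
        contrib = rng.random(num_edges(R))
        roi = region_contributions(contrib, R)
        assert roi.sum() == pytest.approx(2 * contrib.sum())

    def test_matches_incidence_matrix_oracle(self, rng):
        R = 7
        E = num_edges(R)
        contrib = rng.standard_normal(E)
        iu, ju = edge_pairs(R)
        incidence = np.zeros((R, E))
        incidence[iu, np.arange(E)] = 1
        incidence[ju, np.arange(E)] = 1
        np.testing.assert_allclose(
            region_contributions(contrib, R), incidence @ np.abs(contrib), atol=1e-12
        )


def one_hot_affiliation(memberships, M):
    R = len(memberships)
    table = np.zeros((R, M))
    table[np.arange(R), memberships] = 1.0
    return pd.DataFrame(table, columns=[f"NET{m+1}" for m in range(M)])


class TestNetworkIndices:
    def test_intra_network_edge(self):
        aff = one_hot_affiliation([0, 0, 1], 2)
        contrib = np.zeros(3)
        contrib[0] = 1.0  # edge (0,1): both ROIs in network 0
        net = network_indices(contrib, aff)
        assert net.intra[0] == pytest.approx(1.0)
        np.testing.assert_allclose(net.inter, 0.0, atol=1e-12)

    def test_inter_network_edge_halving(self):
        aff = one_hot_affiliation([0, 1, 1], 2)
        contrib = np.zeros(3)
        contrib[0] = 1.0  # edge (0,1) bridges networks 0 and 1
        net = network_indices(contrib, aff)
        assert net.inter[0] == pytest.approx(0.5)
        assert net.inter[1] == pytest.approx(0.5)
        assert net.pairwise[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(net.intra, 0.0, atol=1e-12)

    def test_split_roi_hand_enumeration(self):
        # ROI 0 split 0.6/0.4 over networks 0/1; ROI 1 one-hot network 2
        aff = pd.DataFrame(
            [[0.6, 0.4, 0.0], [0.0, 0.0, 1.0]], columns=["A", "B", "C"]
        )
        contrib = np.array([1.0])
        net = network_indices(contrib, aff)
        assert net.pairwise[0, 2] == pytest.approx(0.6)
        assert net.pairwise[1, 2] == pytest.approx(0.4)
        assert net.inter[2] == pytest.approx(0.5)
        assert net.inter[0] == pytest.approx(0.3)
        assert net.inter[1] == pytest.approx(0.2)
        np.testing.assert_allclose(net.intra, 0.0, atol=1e-12)

    def test_hard_mode_collapses_to_dominant_network(self):
        aff = pd.DataFrame(
            [[0.6, 0.4], [0.6, 0.4]], columns=["A", "B"]
        )
        contrib = np.array([1.0])
        net = network_indices(contrib, aff, mode="hard")
        assert net.intra[0] == pytest.approx(1.0)
        np.testing.assert_allclose(net.inter, 0.0, atol=1e-12)

    @pytest.mark.parametrize("mode", ["soft", "hard"])
    def test_conservation_identities(self, mode, rng):
        R, M = 12, 4
        E = num_edges(R)
        contrib = rng.random(E)
        aff_vals = rng.random((R, M))
        aff = pd.DataFrame(
            aff_vals / aff_vals.sum(1, keepdims=True),
            columns=[f"N{m}" for m in range(M)],
        )
        net = network_indices(contrib, aff, mode=mode)
        total = contrib.sum()
        # B: intra + inter masses sum to the total edge contribution
        assert net.intra.sum() + net.inter.sum() == pytest.approx(total)
        # C: upper-triangle (incl. diagonal) pairwise mass equals the total
        upper = np.triu(net.pairwise).sum()
        assert upper == pytest.approx(total)
        np.testing.assert_allclose(net.pairwise, net.pairwise.T, atol=1e-12)


class TestTopFraction:
    def test_study_sized_top_five_percent(self, rng):
        contrib = np.zeros(6216)
        nz = rng.choice(6216, size=3356, replace=False)
        contrib[nz] = rng.random(3356) + 0.01
        top = top_fraction_edges(contrib, 0.05)
        assert len(top) == 167

    def test_full_fraction_returns_all_nonzero(self, rng):
        contrib = np.concatenate([rng.random(10) + 0.1, np.zeros(5)])
        assert len(top_fraction_edges(contrib, 1.0)) == 10

    def test_tie_at_cut_prefers_lower_edge_id(self):
        contrib = np.array([0.5, 0.9, 0.5, 0.5, 0.0])
        top = top_fraction_edges(contrib, 0.5)  # floor(0.5 * 4) = 2
        assert list(top["edge_id"]) == [1, 0]

    def test_empty_when_no_nonzero(self, caplog):
        with caplog.at_level("WARNING"):
            top = top_fraction_edges(np.zeros(10), 0.05)
        assert len(top) == 0
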