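"""Boundary ligand-receptor test: fractions, scores, permutation p-values."""

import numpy as np
import pandas as pd
import pytest

from scarst import geometry, ligand_receptor as lr, preprocess, synthetic
from scarst.errors import EmptyRegionError
from scarst.matrix import NormalizedMatrix


def make_norm(X, genes=None, spots=None):
    G, S = X.shape
    return NormalizedMatrix(
        genes or [f"g{i:03d}" for i in range(G)],
        spots or [f"b{j:03d}" for j in range(S)],
        X,
    )


class TestExpressionFraction:
    def test_all_zero(self):
        norm = make_norm(np.zeros((2, 5)))
        assert lr.expression_fraction(norm, "g000", norm.spots) == 0.0

    def test_counting(self):
        X = np.zeros((1, 20))
        X[0, :3] = 1.0
        norm = make_norm(X)
        assert lr.expression_fraction(norm, "g000", norm.spots) == pytest.approx(0.15)

    def test_matches_counting_oracle(self, rng):
        X = rng.integers(0, 2, size=(5, 40)).astype(float)
        norm = make_norm(X)
        for gi in range(5):
            expected = (X[gi] > 0).sum() / 40
            assert lr.expression_fraction(norm, f"g{gi:03d}", norm.spots) == expected

    def test_empty_spot_set_raises(self):
        norm = make_norm(np.ones((1, 3)))
        with pytest.raises(EmptyRegionError):
            lr.expression_fraction(norm, "g000", [])


class TestPairFilter:
    @pytest.mark.parametrize(
        "lig,rec,threshold,expected",
        [
            (0.15, 0.2, 0.1, True),
            (0.10, 0.5, 0.1, False),  # strict inequality at the boundary
            (0.5, 0.10, 0.1, False),
            (0.01, 0.01, 0.0, True),
        ],
    )
    def test_strict_threshold(self, lig, rec, threshold, expected):
        assert lr.pair_filter(lig, rec, threshold) is expected


class TestInteractionScore:
    def test_mean_of_two_averages(self):
        X = np.zeros((2, 4))
        X[0, :2] = 2.0  # ligand over ligand spots
        X[1, 2:] = 4.0  # receptor over receptor spots
        norm = make_norm(X)
        pair = lr.LRPair("g000", "g001")
        score = lr.interaction_score(norm, pair, ["b000", "b001"], ["b002", "b003"])
        assert score == pytest.approx(3.0)

    def test_zero_expression_scores_zero(self):
        norm = make_norm(np.zeros((2, 4)))
        pair = lr.LRPair("g000", "g001")
        assert lr.interaction_score(norm, pair, ["b000"], ["b001"]) == 0.0

    def test_matches_two_mean_oracle(self, rng):
        X = rng.random((3, 30))
        norm = make_norm(X)
        pair = lr.LRPair("g001", "g002")
        lig_spots = [f"b{j:03d}" for j in range(10)]
        rec_spots = [f"b{j:03d}" for j in range(10, 30)]
        expected = (X[1, :10].mean() + X[2, 10:].mean()) / 2
        assert lr.interaction_score(norm, pair, lig_spots, rec_spots) == pytest.approx(expected)

    def test_symmetric_under_joint_swap(self, rng):
        X = rng.random((2, 20))
        norm = make_norm(X)
        a = lr.interaction_score(norm, lr.LRPair("g000", "g001"),
                                 [f"b{j:03d}" for j in range(8)],
                                 [f"b{j:03d}" for j in range(8, 20)])
        b = lr.interaction_score(norm, lr.LRPair("g001", "g000"),
                                 [f"b{j:03d}" for j in range(8, 20)],
                                 [f"b{j:03d}" for j in range(8)])
        assert a == pytest.approx(b)


class TestPermutationPvalue:
    def test_constant_gene_gives_p_one(self):
        norm = make_norm(np.full((2, 10), 1.5))
        pair = lr.LRPair("g000", "g001")
        res = lr.permutation_pvalue(
            norm, pair, [f"b{j:03d}" for j in range(5)], [f"b{j:03d}" for j in range(5, 10)],
            n_perm=200, seed=0,
        )
        assert res.p_value == 1.0

    def test_planted_signal_is_significant(self):
        rng = np.random.default_rng(4)
        X = rng.random((2, 60)) * 0.05
        X[0, :30] += 3.0  # ligand only in source spots
        X[1, 30:] += 3.0  # receptor only in target spots
        norm = make_norm(X)
        res = lr.permutation_pvalue(
            norm, lr.LRPair("g000", "g001"),
            [f"b{j:03d}" for j in range(30)], [f"b{j:03d}" for j in range(30, 60)],
            n_perm=1000, seed=1,
        )
        assert res.p_value <= 0.01
        assert res.p_conservative == pytest.approx((res.p_value * 1000 + 1) / 1001)

    def test_deterministic_under_seed(self, rng):
        X = rng.random((2, 24))
        norm = make_norm(X)
        args = (norm, lr.LRPair("g000", "g001"),
                [f"b{j:03d}" for j in range(12)], [f"b{j:03d}" for j in range(12, 24)])
        a = lr.permutation_pvalue(*args, n_perm=300, seed=9)
        b = lr.permutation_pvalue(*args, n_perm=300, seed=9)
        assert a.p_value == b.p_value and a.mean_score == b.mean_score

    def test_invariant_to_gene_renaming_and_spot_order(self, rng):
        X = rng.random((2, 24))
        norm = make_norm(X)
        renamed = make_norm(X, genes=["lig", "rec"])
        spots = [f"b{j:03d}" for j in range(24)]
        a = lr.permutation_pvalue(norm, lr.LRPair("g000", "g001"),
                                  spots[:12], spots[12:], n_perm=300, seed=9)
        b = lr.permutation_pvalue(renamed, lr.LRPair("lig", "rec"),
                                  spots[:12], spots[12:], n_perm=300, seed=9)
        assert a.p_value == b.p_value

    def test_degenerate_interface_raises(self):
        norm = make_norm(np.ones((2, 4)))
        with pytest.raises(EmptyRegionError):
            lr.permutation_pvalue(norm, lr.LRPair("g000", "g001"), ["b000"], ["b001", "b002"])


class TestRunBoundaryLR:
    def test_single_cluster_gives_empty_results(self, lattice_10x10, rng):
        X = rng.integers(0, 3, size=(4, 100))
        norm = make_norm(X, spots=list(lattice_10x10.spot_ids))
        labels = pd.Series("A", index=pd.Index(lattice_10x10.spot_ids))
        graph = geometry.neighbor_graph(lattice_10x10)
        out = lr.run_boundary_lr(norm, labels, graph, [lr.LRPair("g000", "g001")], n_perm=10)
        assert out == []

    def test_both_orderings_reported(self, lattice_10x10, rng):
        X = rng.integers(1, 5, size=(4, 100)).astype(float)
        norm = make_norm(X, spots=list(lattice_10x10.spot_ids))
        labels = pd.Series(
            np.where(lattice_10x10.array_row < 5, "A", "B"),
            index=pd.Index(lattice_10x10.spot_ids),
        )
        graph = geometry.neighbor_graph(lattice_10x10)
        out = lr.run_boundary_lr(norm, labels, graph, [lr.LRPair("g000", "g001")], n_perm=20)
        directions = {(r.source_cluster, r.target_cluster) for r in out}
        assert directions == {("A", "B"), ("B", "A")}

    def test_filtered_pair_reported_without_p(self, lattice_10x10):
        X = np.zeros((2, 100))
        X[0] = 1.0  # ligand everywhere, receptor nowhere
        norm = make_norm(X, spots=list(lattice_10x10.spot_ids))
        labels = pd.Series(
            np.where(lattice_10x10.array_row < 5, "A", "B"),
            index=pd.Index(lattice_10x10.spot_ids),
        )
        graph = geometry.neighbor_graph(lattice_10x10)
        out = lr.run_boundary_lr(norm, labels, graph, [lr.LRPair("g000", "g001")], n_perm=20)
        assert out and all(r.p_value is None for r in out)

    def test_planted_pair_tops_its_cluster_pair(self, scene14, norm14, graph_30x30):
        """The planted fibroblast->microglia ligand-receptor signal attains the
        maximal mean score among decoy pairs tested on that boundary."""
        decoys = [lr.LRPair(f"Gene{i:05d}", f"Gene{i+1:05d}") for i in range(0, 40, 2)]
        pairs = [lr.LRPair("Psap", "Gpr37l1")] + decoys
        out = lr.run_boundary_lr(
            norm14, scene14.truth_labels, graph_30x30, pairs, n_perm=100, seed=5
        )
        fm = [r for r in out if (r.source_cluster, r.target_cluster) == ("fibroblast", "microglia")]
        assert fm
        best = max(fm, key=lambda r: r.mean_score)
        assert best.pair.pair_name == "Psap_Gpr37l1"
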