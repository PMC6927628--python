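import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix

from hybriddetect import (MarkerMatrix, bootstrap_support, dice_similarity,
                          distance_matrix, nj, pcoa, upgma)
from hybriddetect.errors import HybridDetectError, UndefinedSimilarityError


def random_matrix(rng, n, m, ensure_presence=True):
    vals = rng.integers(0, 2, (n, m))
    if ensure_presence:
        vals[:, 0] = 1
    return MarkerMatrix([f"s{i}" for i in range(n)], [f"L{j}" for j in range(m)], vals)


class TestDice:
    def test_hand_counted_example(self):
        # a=2 shared, b=1, c=1 exclusive -> S = 4/6
        assert dice_similarity([1, 1, 0, 1], [1, 0, 1, 1]) == pytest.approx(2 / 3)

    def test_identity_and_disjoint(self):
        assert dice_similarity([1, 0, 1], [1, 0, 1]) == 1.0
        assert dice_similarity([1, 1, 0, 0], [0, 0, 1, 1]) == 0.0

    def test_both_all_absent_undefined(self):
        with pytest.raises(UndefinedSimilarityError):
            dice_similarity([0, 0], [0, 0])

    def test_symmetry_and_bounds_over_random_pairs(self, rng):
        for _ in range(1000):
            x = rng.integers(0, 2, 20)
            y = rng.integers(0, 2, 20)
            if x.sum() == 0 and y.sum() == 0:
                continue
            s = dice_similarity(x, y)
            assert s == dice_similarity(y, x)
            assert 0.0 <= s <= 1.0

    def test_distance_is_one_minus_similarity(self, rng):
        mat = random_matrix(rng, 6, 30)
        dm = distance_matrix(mat)
        for i, j in itertools.combinations(range(6), 2):
            s = dice_similarity(mat.values[i], mat.values[j])
            assert dm.data[i, j] == pytest.approx(1 - s, abs=1e-12)

    def test_identical_specimens_distance_zero(self):
        mat = MarkerMatrix(["s1", "s2"], ["L1", "L2"], [[1, 0], [1, 0]])
        assert distance_matrix(mat).data[0, 1] == 0.0

    def test_bounded_for_random_matrices(self, rng):
        for _ in range(100):
            dm = distance_matrix(random_matrix(rng, 5, 15))
            assert (dm.data >= 0).all() and (dm.data <= 1).all()


class TestUPGMA:
    def test_hand_worked_three_taxa(self):
        dm = DistanceMatrix([[0, 2, 8], [2, 0, 8], [8, 8, 0]], ["A", "B", "C"])
        tree = upgma(dm)
        dists = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
        # ((A:1,B:1):3,C:4): every tip at depth 4, A-B split at height 1
        assert all(abs(d - 4.0) < 1e-9 for d in dists.values())
        ab = tree.lowest_common_ancestor(["A", "B"])
        assert ab.accumulate_to_ancestor(tree) == pytest.approx(3.0)

    def test_two_taxa_cherry(self):
        dm = DistanceMatrix([[0, 0.5], [0.5, 0]], ["A", "B"])
        tree = upgma(dm)
        for t in tree.tips():
            assert t.length == pytest.approx(0.25)

    def test_ultrametric_on_random_inputs(self, rng):
        for _ in range(10):
            mat = random_matrix(rng, 6, 40)
            tree = upgma(distance_matrix(mat))
            depths = [t.accumulate_to_ancestor(tree) for t in tree.tips()]
            assert max(depths) - min(depths) < 1e-9

    def test_average_linkage_heights_against_brute_force(self, rng):
        """UPGMA merge heights equal half the average inter-cluster distance."""
        D = distance_matrix(random_matrix(rng, 5, 30))
        tree = upgma(D)
        ids = list(D.ids)
        # brute-force agglomeration
        clusters = [{i} for i in ids]
        heights = []
        while len(clusters) > 1:
            best = min(
                itertools.combinations(range(len(clusters)), 2),
                key=lambda p: np.mean([D[a, b] for a in clusters[p[0]] for b in clusters[p[1]]]),
            )
            i, j = best
            h = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]]) / 2
            heights.append((frozenset(clusters[i] | clusters[j]), h))
            clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [
                clusters[i] | clusters[j]
            ]
        for members, h in heights:
            node = tree.lowest_common_ancestor(sorted(members))
            depth = max(t.accumulate_to_ancestor(node) for t in node.tips())
            assert depth == pytest.approx(h, abs=1e-9)

    def test_n1_is_error(self):
        with pytest.raises(HybridDetectError):
            upgma(DistanceMatrix([[0.0]], ["A"]))


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix([[0, 2, 8], [2, 0, 8], [8, 8, 0]], ["A", "B", "C"])
        tree = nj(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 7.0})

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        D = {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }
        ids = ["A", "B", "C", "D"]
        mat = np.zeros((4, 4))
        for (x, y), d in D.items():
            i, j = ids.index(x), ids.index(y)
            mat[i, j] = mat[j, i] = d
        tree = nj(DistanceMatrix(mat, ids))
        tt = tree.tip_tip_distances()
        for (x, y), d in D.items():
            assert tt[x, y] == pytest.approx(d, abs=1e-9)

    def test_tip_permutation_gives_same_topology(self, rng):
        mat = random_matrix(rng, 6, 40)
        dm = distance_matrix(mat)
        order = list(rng.permutation(dm.ids))
        t1 = nj(dm)
        t2 = nj(dm.filter(order))
        assert t1.compare_rfd(t2) == 0.0

    def test_negative_branches_clamped(self):
        # strongly non-additive matrix provokes negative NJ branch estimates
        dm = DistanceMatrix(
            [[0, 1, 1, 1.9], [1, 0, 1.9, 1], [1, 1.9, 0, 1], [1.9, 1, 1, 0]],
            ["A", "B", "C", "D"],
        )
        tree = nj(dm)
        assert all(n.length >= 0 for n in tree.traverse() if n.length is not None)

    def test_fewer_than_three_is_error(self):
        with pytest.raises(HybridDetectError):
            nj(DistanceMatrix([[0, 1], [1, 0]], ["A", "B"]))


class TestBootstrap:
    def _matrix(self, rng):
        # a1 == a2 exactly; b group far away
        a = rng.integers(0, 2, 30)
        a[0] = 1
        b1 = 1 - a
        b1[0] = 1
        b2 = b1.copy()
        b2[5:8] ^= 1
        c = rng.integers(0, 2, 30)
        c[0] = 1
        return MarkerMatrix(
            ["a1", "a2", "b1", "b2", "c1"],
            [f"L{j}" for j in range(30)],
            np.vstack([a, a, b1, b2, c]),
        )

    @pytest.mark.parametrize("method", ["nj", "upgma"])
    def test_identical_pair_supported_at_100(self, rng, method):
        tree = bootstrap_support(self._matrix(rng), method=method, n_reps=50, seed=1)
        node = tree.lowest_common_ancestor(["a1", "a2"])
        assert node.name == "100"

    def test_single_replicate_supports_are_0_or_100(self, rng):
        tree = bootstrap_support(self._matrix(rng), method="nj", n_reps=1, seed=2)
        supports = [int(n.name) for n in tree.non_tips(include_self=False) if n.name]
        assert supports and all(s in (0, 100) for s in supports)

    def test_same_seed_reproduces_supports(self, rng):
        mat = self._matrix(rng)
        t1 = bootstrap_support(mat, method="nj", n_reps=25, seed=7)
        t2 = bootstrap_support(mat, method="nj", n_reps=25, seed=7)
        assert str(t1) == str(t2)


class TestPCoA:
    def test_two_specimens_closed_form(self):
        dm = DistanceMatrix([[0, 0.4], [0.4, 0]], ["A", "B"])
        res = pcoa(dm, n_axes=1)
        assert res.proportion_explained[0] == pytest.approx(1.0)
        assert sorted(res.coordinates[:, 0]) == pytest.approx([-0.2, 0.2])

    def test_three_equidistant_split_evenly(self):
        dm = DistanceMatrix([[0, 1, 1], [1, 0, 1], [1, 1, 0]], ["A", "B", "C"])
        res = pcoa(dm, n_axes=2)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
        assert res.proportion_explained == pytest.approx([0.5, 0.5])

    def test_euclidean_embedding_reproduces_distances(self, rng):
        pts = rng.normal(size=(7, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(DistanceMatrix(D, [f"s{i}" for i in range(7)]), n_axes=3)
        rec = np.linalg.norm(
            res.coordinates[:, None] - res.coordinates[None, :], axis=2
        )
        assert np.abs(rec - D).max() < 1e-8

    def test_axes_truncated_with_warning(self):
        dm = DistanceMatrix([[0, 0.4], [0.4, 0]], ["A", "B"])
        with pytest.warns(UserWarning, match="truncating"):
            res = pcoa(dm, n_axes=5)
        assert res.coordinates.shape[1] == 1

    def test_matches_reference_ordination(self, rng):
        """Cross-check positive eigenvalues against scikit-bio's PCoA."""
        from skbio.stats.ordination import pcoa as skbio_pcoa

        mat = random_matrix(rng, 8, 40)
        dm = distance_matrix(mat)
        ours = pcoa(dm, n_axes=3)
        ref = skbio_pcoa(dm, number_of_dimensions=3)
        assert ours.eigenvalues == pytest.approx(
            np.asarray(ref.eigvals)[:3], rel=1e-8
        )
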