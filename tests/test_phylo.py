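from itertools import combinations

import numpy as np
import pytest

from rgacnv.io import GenotypeMatrix
from rgacnv.phylo import (
    genotype_distance,
    neighbor_joining,
    read_newick,
    robinson_foulds,
    tree_to_newick,
)
from rgacnv.simulate import evolve_genotypes, random_tree


def gm(samples, rows):
    return GenotypeMatrix(
        samples, [f"snp{i}" for i in range(len(rows))], np.array(rows, dtype=np.int8)
    )


def leaf_distances(tree):
    """Pairwise path lengths between leaves."""
    terminals = tree.get_terminals()
    return {
        frozenset((a.name, b.name)): tree.distance(a, b)
        for a, b in combinations(terminals, 2)
    }


class TestGenotypeDistance:
    def test_identical_rows_give_zero(self):
        m = gm(["a", "b"], [[0, 0], [2, 2], [1, 1]])
        D, _ = genotype_distance(m)
        assert D[0, 1] == 0.0

    def test_opposite_homozygotes_give_one(self):
        m = gm(["a", "b"], [[0, 2], [0, 2], [2, 0]])
        D, _ = genotype_distance(m)
        assert D[0, 1] == 1.0

    def test_missing_sites_are_excluded_pairwise(self):
        # rows are sites: a = (0,1,2,.), b = (0,1,0,1)
        m = gm(["a", "b"], [[0, 0], [1, 1], [2, 0], [-1, 1]])
        D, _ = genotype_distance(m)
        assert D[0, 1] == pytest.approx(1 / 3)

    def test_no_coobserved_sites_names_the_pair(self):
        m = gm(["a", "b"], [[0, -1], [-1, 2]])
        with pytest.raises(ValueError, match="'a' and 'b'"):
            genotype_distance(m)


class TestNeighborJoining:
    def test_two_taxa_edge_length(self):
        D = np.array([[0.0, 0.4], [0.4, 0.0]])
        tree = neighbor_joining(D, ["a", "b"])
        d = leaf_distances(tree)
        assert d[frozenset(("a", "b"))] == pytest.approx(0.4)

    def test_three_taxa_closed_form(self):
        # ultrametric: d(A,B)=2, d(A,C)=d(B,C)=4 -> lengths A:1, B:1, C:3
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = neighbor_joining(D, ["A", "B", "C"])
        lengths = {t.name: t.branch_length for t in tree.get_terminals()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_four_taxa_additive_exact_recovery(self):
        """NJ reproduces a 4-taxon additive matrix exactly; the oracle
        enumerates all three unrooted quartet topologies and least-squares
        fits branch lengths — only the true split has zero residual."""
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        names = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )

        # oracle: for split (x,y | z,w) solve for 5 edges via least squares
        def residual(split):
            (x, y), (z, w) = split
            # edges: ex, ey, ez, ew, internal
            rows, rhs = [], []
            idx = {names[i]: i for i in range(4)}
            e_of = {x: 0, y: 1, z: 2, w: 3}
            for a, b in combinations(names, 2):
                row = [0.0] * 5
                row[e_of[a]] = 1
                row[e_of[b]] = 1
                same_side = {a, b} in ({x, y}, {z, w})
                if not same_side:
                    row[4] = 1
                rows.append(row)
                rhs.append(D[idx[a], idx[b]])
            sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
            fitted = np.array(rows) @ sol
            return float(np.sum((fitted - np.array(rhs)) ** 2)), sol

        splits = [
            (("A", "B"), ("C", "D")),
            (("A", "C"), ("B", "D")),
            (("A", "D"), ("B", "C")),
        ]
        residuals = {s: residual(s)[0] for s in splits}
        zero = [s for s, r in residuals.items() if r < 1e-18]
        assert zero == [(("A", "B"), ("C", "D"))]
        _, sol = residual(zero[0])
        assert sol == pytest.approx([1, 2, 3, 4, 1])

        tree = neighbor_joining(D, names)
        truth = read_newick("((A:1,B:2):1,(C:3,D:4):0);")
        assert robinson_foulds(tree, truth) == 0
        d = leaf_distances(tree)
        for a, b in combinations(names, 2):
            i, j = names.index(a), names.index(b)
            assert d[frozenset((a, b))] == pytest.approx(D[i, j])

    def test_additive_matrices_recover_topology(self):
        """Atteson consistency at zero noise: distances measured along a
        random tree are reproduced as that tree's topology."""
        rng = np.random.default_rng(10)
        for trial in range(20):
            n = int(rng.integers(4, 11))
            names = [f"t{i}" for i in range(n)]
            truth = read_newick(random_tree(names, rng))
            D = np.zeros((n, n))
            terms = {t.name: t for t in truth.get_terminals()}
            for i, j in combinations(range(n), 2):
                D[i, j] = D[j, i] = truth.distance(terms[names[i]], terms[names[j]])
            tree = neighbor_joining(D, names)
            assert robinson_foulds(tree, truth) == 0

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(np.array([[0, 1], [2, 0]], dtype=float), ["a", "b"])
        with pytest.raises(ValueError, match="non-negative"):
            neighbor_joining(np.array([[0, -1], [-1, 0]], dtype=float), ["a", "b"])
        with pytest.raises(ValueError, match="diagonal"):
            neighbor_joining(np.array([[1, 1], [1, 0]], dtype=float), ["a", "b"])

    def test_matches_scikit_bio_on_noisy_matrix(self):
        """Independent implementation cross-check: skbio's NJ yields the
        same topology on a perturbed additive matrix."""
        skbio = pytest.importorskip("skbio")
        from io import StringIO

        rng = np.random.default_rng(12)
        names = [f"t{i}" for i in range(8)]
        truth = read_newick(random_tree(names, rng))
        terms = {t.name: t for t in truth.get_terminals()}
        n = len(names)
        D = np.zeros((n, n))
        for i, j in combinations(range(n), 2):
            d = truth.distance(terms[names[i]], terms[names[j]])
            D[i, j] = D[j, i] = d * (1 + rng.uniform(-0.05, 0.05))
        mine = neighbor_joining(D, names)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids=names))
        theirs_tree = read_newick(str(theirs))
        assert robinson_foulds(mine, theirs_tree) == 0


class TestNewick:
    def test_round_trip_preserves_topology_and_lengths(self):
        rng = np.random.default_rng(13)
        names = [f"t{i}" for i in range(9)]
        truth = read_newick(random_tree(names, rng))
        terms = {t.name: t for t in truth.get_terminals()}
        n = len(names)
        D = np.zeros((n, n))
        for i, j in combinations(range(n), 2):
            D[i, j] = D[j, i] = truth.distance(terms[names[i]], terms[names[j]])
        tree = neighbor_joining(D, names)
        again = read_newick(tree_to_newick(tree))
        assert robinson_foulds(tree, again) == 0
        d1, d2 = leaf_distances(tree), leaf_distances(again)
        for key in d1:
            assert d2[key] == pytest.approx(d1[key], rel=1e-9)

    def test_rf_matches_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(14)
        names = [f"t{i}" for i in range(10)]
        for _ in range(10):
            nwk1, nwk2 = random_tree(names, rng), random_tree(names, rng)
            mine = robinson_foulds(read_newick(nwk1), read_newick(nwk2))
            tns = dendropy.TaxonNamespace()
            t1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=tns)
            t2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=tns)
            t1.encode_bipartitions()
            t2.encode_bipartitions()
            theirs = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
            assert mine == theirs


class TestGenotypeSimulationRecovery:
    def test_single_seed_recovery(self):
        rng = np.random.default_rng(15)
        names = [f"s{i}" for i in range(8)]
        nwk = random_tree(names, rng)
        gmat = evolve_genotypes(nwk, names, 5000, rng)
        D, order = genotype_distance(gmat)
        tree = neighbor_joining(D, order)
        assert robinson_foulds(tree, read_newick(nwk)) == 0
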