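"""Sample phylogeny from biallelic genotypes: distances + neighbour joining.

The pairwise distance between two samples is the mean allele difference per
co-observed site, ``mean(|g_i − g_j|) / 2`` over sites where neither call
is missing — a bounded [0, 1] dissimilarity tolerant of missing data.

The tree is built with the Saitou–Nei neighbour-joining algorithm: at each
step the pair minimising ``Q(i,j) = (n−2) d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)``
is joined, branch lengths follow the standard split formula, and the matrix
is reduced with ``d(u,k) = (d(i,k) + d(j,k) − d(i,j)) / 2``. Ties in Q are
broken by the smallest (i, j) index pair; negative branch-length estimates
are clamped to zero with the pre-clamp value logged. The result is left
unrooted (the final join produces a trifurcation for n ≥ 3) and serialised
as newick via Bio.Phylo.
"""

from __future__ import annotations

import logging
from io import StringIO
from pathlib import Path

import numpy as np
from Bio import Phylo
from Bio.Phylo.BaseTree import Clade, Tree

from .io import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "genotype_distance",
    "neighbor_joining",
    "write_newick",
    "read_newick",
    "tree_to_newick",
    "robinson_foulds",
]


def genotype_distance(gm: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    """Pairwise allele-difference distances between all samples.

    Returns the symmetric matrix (zero diagonal) and the sample order.
    Raises if any pair has no co-observed site.
    """
    data = gm.data  # (n_sites, n_samples)
    n = len(gm.samples)
    D = np.zeros((n, n))
    observed = data >= 0
    for i in range(n):
        for j in range(i + 1, n):
            co = observed[:, i] & observed[:, j]
            n_co = int(co.sum())
            if n_co == 0:
                raise ValueError(
                    f"samples {gm.samples[i]!r} and {gm.samples[j]!r} share no "
                    "co-observed site"
                )
            d = np.abs(data[co, i].astype(int) - data[co, j].astype(int)).mean() / 2.0
            D[i, j] = D[j, i] = d
    return D, list(gm.samples)


def _validate_distance_matrix(D: np.ndarray) -> None:
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if (D < 0).any():
        raise ValueError("distance matrix must be non-negative")


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.info("clamping negative branch length %.6g to 0 at %s", length, context)
        return 0.0
    return length


def neighbor_joining(D: np.ndarray, names: list[str]) -> Tree:
    """Saitou–Nei neighbour joining over a distance matrix.

    Returns an unrooted Bio.Phylo tree: for n ≥ 3 the root clade is the
    trifurcation left by the final agglomeration step; for n = 2 the two
    leaves hang off the root with half the pairwise distance each, so the
    leaf-to-leaf path length equals d(1,2).
    """
    D = np.asarray(D, dtype=float)
    _validate_distance_matrix(D)
    n = D.shape[0]
    if n != len(names):
        raise ValueError("names length must match matrix size")
    if n < 2:
        raise ValueError("neighbour joining needs ≥2 taxa")

    nodes: list[Clade] = [Clade(name=str(nm)) for nm in names]
    if n == 2:
        for node in nodes:
            node.branch_length = D[0, 1] / 2.0
        tree = Tree(root=Clade(clades=nodes), rooted=False)
        return tree

    active = list(range(n))
    dist = D.copy()

    while len(active) > 3:
        m = len(active)
        sums = dist[np.ix_(active, active)].sum(axis=1)
        best = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * dist[active[ai], active[aj]] - sums[ai] - sums[aj]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (ai, aj)
        ai, aj = best  # type: ignore[misc]
        i, j = active[ai], active[aj]
        dij = dist[i, j]
        li = 0.5 * dij + (sums[ai] - sums[aj]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].branch_length = _clamp(li, f"join({names_of(nodes[i])})")
        nodes[j].branch_length = _clamp(lj, f"join({names_of(nodes[j])})")
        new = Clade(clades=[nodes[i], nodes[j]])

        # grow matrix/node list with the new internal node
        new_idx = dist.shape[0]
        grown = np.zeros((new_idx + 1, new_idx + 1))
        grown[:new_idx, :new_idx] = dist
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist[i, k] + dist[j, k] - dij)
            grown[new_idx, k] = grown[k, new_idx] = duk
        dist = grown
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # final trifurcation: three-point closed-form lengths
    a, b, c = active
    dab, dac, dbc = dist[a, b], dist[a, c], dist[b, c]
    nodes[a].branch_length = _clamp(0.5 * (dab + dac - dbc), "final")
    nodes[b].branch_length = _clamp(0.5 * (dab + dbc - dac), "final")
    nodes[c].branch_length = _clamp(0.5 * (dac + dbc - dab), "final")
    root = Clade(clades=[nodes[a], nodes[b], nodes[c]])
    return Tree(root=root, rooted=False)


def names_of(clade: Clade) -> str:
    return ",".join(sorted(t.name for t in clade.get_terminals()))


def tree_to_newick(tree: Tree) -> str:
    buf = StringIO()
    Phylo.write(tree, buf, "newick", format_branch_length="%.10g")
    return buf.getvalue()


def write_newick(tree: Tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree))


def read_newick(source: str | Path) -> Tree:
    """Read a newick tree from a path or a newick string."""
    text = str(source)
    if "(" not in text:
        text = Path(source).read_text()
    return Phylo.read(StringIO(text), "newick")


def _bipartitions(tree: Tree) -> set[frozenset[str]]:
    """Non-trivial splits, each normalised to the side not containing the
    lexicographically smallest leaf (so rootings compare equal)."""
    leaves = {t.name for t in tree.get_terminals()}
    anchor = min(leaves)
    splits: set[frozenset[str]] = set()
    for clade in tree.get_nonterminals():
        side = {t.name for t in clade.get_terminals()}
        if anchor in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(frozenset(side))
    return splits


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Unweighted Robinson–Foulds distance (symmetric difference of the
    non-trivial bipartition sets). Both trees must share one leaf set."""
    l1 = {t.name for t in t1.get_terminals()}
    l2 = {t.name for t in t2.get_terminals()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    s1, s2 = _bipartitions(t1), _bipartitions(t2)
    return len(s1 ^ s2)
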