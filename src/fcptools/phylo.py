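"""Distances, neighbor-joining cladograms, bootstrap supports, and
clade-based Lhcf group assignment.

Distances are protein p-distances with pairwise deletion, corrected with
the 20-state Jukes-Cantor model

    d = -(19/20) * ln(1 - (20/19) * p)

which assumes equal exchange rates among the twenty amino acids (the same
assumption the synthetic sequence evolver makes, so simulated p-distances
are analytically recoverable).  Trees are built by canonical
neighbor-joining with a deterministic lexicographic tie-break and negative
branch lengths clamped to zero.  Bootstrap support of an internal edge is
the percentage of column-resampled replicate trees containing the same
bipartition.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode

from .msa import MSA

logger = logging.getLogger(__name__)

MAX_P = 19.0 / 20.0

LINEAGES = ("haptophyte", "diatom", "seaweed")
LHCF_GROUPS = ("A", "B", "C", "D")


def p_distance(msa: MSA, i: str, j: str) -> float:
    """Fraction of differing residues over columns where neither row is
    gapped (pairwise deletion)."""
    a, b = msa.row(i), msa.row(j)
    shared = diff = 0
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            shared += 1
            if x != y:
                diff += 1
    if shared == 0:
        raise ValueError(f"rows {i!r} and {j!r} share no ungapped column")
    return diff / shared


def jukes_cantor(p: float, clamp: bool = False) -> float:
    """20-state Jukes-Cantor correction of a protein p-distance.

    ``p`` must be below the saturation point 19/20; with ``clamp=True``
    saturated values are pulled just below it (used inside bootstrap
    replicates where individual resamples can saturate).
    """
    if p < 0:
        raise ValueError("p-distance cannot be negative")
    if p >= MAX_P:
        if not clamp:
            raise ValueError(
                f"p-distance {p} at or beyond saturation (19/20)"
            )
        p = MAX_P - 1e-4
    return -(19.0 / 20.0) * math.log1p(-(20.0 / 19.0) * p)


def pdistance_matrix(msa: MSA) -> DistanceMatrix:
    """All-pairs p-distance matrix (pairwise deletion), vectorised."""
    X = msa.encoded()
    present = X >= 0
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        shared = present[i] & present[i + 1 :]
        nshared = shared.sum(axis=1)
        if (nshared == 0).any():
            j = int(np.argmax(nshared == 0)) + i + 1
            raise ValueError(
                f"rows {msa.ids[i]!r} and {msa.ids[j]!r} share no ungapped column"
            )
        ndiff = (shared & (X[i] != X[i + 1 :])).sum(axis=1)
        d[i, i + 1 :] = ndiff / nshared
    d = d + d.T
    return DistanceMatrix(d, ids=msa.ids)


def jc_distance_matrix(msa: MSA, clamp: bool = False) -> DistanceMatrix:
    pd = pdistance_matrix(msa)
    d = pd.data.copy()
    n = d.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jukes_cantor(d[i, j], clamp=clamp)
    return DistanceMatrix(d, ids=list(pd.ids))


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbor-joining on a distance matrix.

    Ties in the Q criterion break to the pair whose (sorted) representative
    leaf names are lexicographically smallest, so the topology is fully
    deterministic.  Negative branch lengths are clamped to zero and the
    clamped deficit logged.  The returned tree is unrooted, serialised as a
    trifurcation at the root.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    D = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    reps: list[str] = list(ids)  # smallest leaf name per active node

    def clamped(x: float) -> float:
        if x < 0:
            logger.debug("clamping negative branch length %.4g to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        r = len(nodes)
        sums = D.sum(axis=1)
        Q = (r - 2) * D - sums[:, None] - sums[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((reps[i], reps[j]))), i, j)
            for i, j in cand
            if i < j
        )
        _, i, j = best
        li = clamped(0.5 * D[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2)))
        lj = clamped(D[i, j] - (0.5 * D[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2))))
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        newd = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.zeros((r - 1, r - 1))
        D2[: r - 2, : r - 2] = D[np.ix_(keep, keep)]
        D2[-1, : r - 2] = D2[: r - 2, -1] = newd[keep]
        D = D2
        newrep = min(reps[i], reps[j])
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [newrep]

    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = clamped(0.5 * (dab + dac - dbc))
    b.length = clamped(0.5 * (dab + dbc - dac))
    c.length = clamped(0.5 * (dac + dbc - dab))
    order = np.argsort(reps, kind="stable")
    root = TreeNode(children=[nodes[k] for k in order])
    root.length = None
    return root


def _bipartitions(tree: TreeNode, all_tips: frozenset[str],
                  ref: str) -> set[frozenset[str]]:
    """Non-trivial bipartitions, canonicalised to the side not holding the
    reference taxon (unrooted comparison)."""
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        if 1 < len(side) < len(all_tips) - 1:
            parts.add(side)
    return parts


def nj_tree(msa: MSA, clamp: bool = False) -> TreeNode:
    """p-distance -> Jukes-Cantor -> neighbor-joining on an alignment."""
    return neighbor_joining(jc_distance_matrix(msa, clamp=clamp))


def bootstrap_support(msa: MSA, n_reps: int = 100, seed: int = 0) -> TreeNode:
    """Neighbor-joining cladogram with bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; each replicate
    is taken through distances and NJ, and every internal edge of the main
    tree is annotated with the percentage of replicates containing its
    bipartition (``node.support``).  Replicate RNG streams derive from one
    root seed by replicate counter, so runs are reproducible.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(msa.ids) < 4:
        raise ValueError("bootstrap supports need at least 4 sequences")
    if pdistance_matrix(msa).data.max() == 0.0:
        raise ValueError("alignment has no signal: all rows identical")
    main = nj_tree(msa)
    all_tips = frozenset(msa.ids)
    ref = min(all_tips)
    counts: dict[frozenset[str], int] = {}
    ncol = msa.n_columns
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        cols = rng.integers(0, ncol, size=ncol)
        rows = [(i, "".join(s[c] for c in cols)) for i, s in msa.records]
        try:
            rtree = nj_tree(MSA(rows), clamp=True)
        except ValueError:
            continue  # e.g. a resample leaves two rows with no shared column
        for part in _bipartitions(rtree, all_tips, ref):
            counts[part] = counts.get(part, 0) + 1
    for node in main.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        if 1 < len(side) < len(all_tips) - 1:
            node.support = 100.0 * counts.get(side, 0) / n_reps
    return main


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Midpoint-rooted copy, for display and for reading clades off a
    cladogram (the NJ root placement is otherwise arbitrary)."""
    return tree.root_at_midpoint()


def write_newick(tree: TreeNode, path, supports: bool = True) -> None:
    """Serialise with integer bootstrap supports as internal node labels."""
    t = tree.copy()
    if supports:
        for node in t.non_tips(include_self=False):
            sup = getattr(node, "support", None)
            if sup is not None:
                node.name = str(int(round(sup)))
    t.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def assign_lhcf_groups(
    tree: TreeNode,
    species_class: Mapping[str, str],
    min_support: float = 50.0,
    min_size: int = 3,
) -> dict[str, str]:
    """Label Lhcf leaves with groups A-D from the cladogram.

    Walking top-down, each maximal clade with enough leaves and support is
    labelled by lineage composition: all-haptophyte -> B, all-diatom -> C,
    all-seaweed -> D, haptophyte-majority mixtures containing at least one
    diatom -> A.  Clades without support annotation (e.g. no bootstrap run)
    are treated as supported.  Leaves outside any qualifying clade are
    ``unassigned``.
    """
    tips = [t.name for t in tree.tips()]
    for tip in tips:
        if species_class.get(tip) not in LINEAGES:
            raise ValueError(f"leaf {tip!r} has no lineage classification")
    labels: dict[str, str] = {t: "unassigned" for t in tips}

    def group_for(composition: dict[str, int]) -> str | None:
        kinds = {k for k, v in composition.items() if v > 0}
        if kinds == {"haptophyte"}:
            return "B"
        if kinds == {"diatom"}:
            return "C"
        if kinds == {"seaweed"}:
            return "D"
        total = sum(composition.values())
        if (
            composition.get("haptophyte", 0) * 2 > total
            and composition.get("diatom", 0) >= 1
        ):
            return "A"
        return None

    def walk(node) -> None:
        for child in node.children:
            if child.is_tip():
                continue
            sup = getattr(child, "support", None)
            clade_tips = [t.name for t in child.tips()]
            if len(clade_tips) >= min_size and (
                sup is None or sup >= min_support
            ):
                comp: dict[str, int] = {}
                for t in clade_tips:
                    comp[species_class[t]] = comp.get(species_class[t], 0) + 1
                group = group_for(comp)
                if group is not None:
                    for t in clade_tips:
                        labels[t] = group
                    continue
            walk(child)

    walk(tree)
    return labels


__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "p_distance",
    "jukes_cantor",
    "pdistance_matrix",
    "jc_distance_matrix",
    "neighbor_joining",
    "nj_tree",
    "bootstrap_support",
    "write_newick",
    "read_newick",
    "assign_lhcf_groups",
]
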