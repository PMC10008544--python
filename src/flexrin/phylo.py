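"""Structure-snapshot trees: pairwise RMSD matrix -> neighbor joining -> Newick.

A population of conformers (trajectory snapshots, predicted models) can be
compared by all-pairs superposed Cα RMSD; the resulting distance matrix is
turned into an unrooted tree with the Saitou-Nei neighbor-joining
algorithm, which is exact on additive distances.  Branch lengths use the
standard NJ formulas; negative lengths (possible on non-additive input) are
clamped to zero with a warning.  Trees serialize to plain Newick.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import MismatchError, ParameterError
from .flexibility import superpose
from .structure import StructureFrame

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, float)
        n = len(self.labels)
        if M.shape != (n, n):
            raise MismatchError("matrix shape does not match labels")
        if not np.all(np.isfinite(M)):
            raise ParameterError("distances must be finite")
        if not np.allclose(M, M.T, atol=1e-9):
            raise ParameterError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(M)) > 1e-9):
            raise ParameterError("diagonal must be zero")
        self.matrix = M

    def summary(self) -> tuple[float, float]:
        """Mean ± s.d. over the strict upper-triangle entries."""
        iu = np.triu_indices(len(self.labels), k=1)
        vals = self.matrix[iu]
        return float(vals.mean()), float(vals.std())


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; ``length`` is the branch to the parent."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        return [lf for c in self.children for lf in c.leaves()]


@dataclass
class PhyloTree:
    """Unrooted tree represented with an arbitrary internal root node."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return sorted(lf.name for lf in self.root.leaves())

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions (splits), as frozensets of one side.

        Canonicalized so that comparing two trees over the same leaf set is
        a set comparison.
        """
        all_leaves = frozenset(self.leaf_names())
        splits: set[frozenset] = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                splits.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        walk(self.root)
        return splits


def pairwise_rmsd_matrix(frames: list[StructureFrame]) -> DistanceMatrix:
    """All-pairs Cα RMSD after Kabsch superposition, computed once per pair."""
    if len(frames) < 3:
        raise ParameterError("need at least 3 frames")
    keys = frames[0].residue_keys
    for f in frames[1:]:
        if f.residue_keys != keys:
            raise MismatchError(
                f"frame {f.frame_label!r} has different polymer topology; "
                "align/pair the frames first"
            )
    coords = [f.ca_coords() for f in frames]
    n = len(frames)
    M = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        _, r = superpose(coords[j], coords[i])
        M[i, j] = M[j, i] = r
    return DistanceMatrix([f.frame_label for f in frames], M)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei NJ with deterministic tie-breaking.

    Joins the pair minimizing Q(i,j) = (n-2) d(i,j) - sum_k d(i,k)
    - sum_k d(j,k); ties break on the lexicographically smallest sorted
    label pair (each active node represented by its smallest leaf label).
    Exact (topology and branch lengths) on additive matrices.
    """
    n = len(dm.labels)
    if n < 3:
        raise ParameterError("NJ needs at least 3 labels")
    D = dm.matrix.copy()
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in dm.labels]
    reps: list[str] = list(dm.labels)  # smallest leaf label per active node
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            if x < -1e-9:
                logger.warning("negative NJ branch length %.3g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ia, ib in itertools.combinations(active, 2):
            q = (m - 2) * D[ia, ib] - sums[ia] - sums[ib]
            tie = tuple(sorted((reps[ia], reps[ib])))
            cand = (q, tie, ia, ib)
            if best is None or cand[:2] < best[:2]:
                best = cand
        _, _, ia, ib = best
        li = clamp(0.5 * D[ia, ib] + (sums[ia] - sums[ib]) / (2 * (m - 2)))
        lj = clamp(D[ia, ib] - (0.5 * D[ia, ib] + (sums[ia] - sums[ib]) / (2 * (m - 2))))
        child_i, child_j = nodes[ia], nodes[ib]
        child_i.length, child_j.length = li, lj
        new = TreeNode(children=[child_i, child_j])

        # grow matrix by one row/col for the new node
        row = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (ia, ib):
                continue
            row[k] = 0.5 * (D[ia, k] + D[ib, k] - D[ia, ib])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = row[:-1]
        D[:-1, -1] = row[:-1]
        nodes.append(new)
        reps.append(min(reps[ia], reps[ib]))
        active = [k for k in active if k not in (ia, ib)] + [len(nodes) - 1]

    # final three-way join
    ia, ib, ic = active
    la = clamp(0.5 * (D[ia, ib] + D[ia, ic] - D[ib, ic]))
    lb = clamp(0.5 * (D[ia, ib] + D[ib, ic] - D[ia, ic]))
    lc = clamp(0.5 * (D[ia, ic] + D[ib, ic] - D[ia, ib]))
    for idx, ln in zip((ia, ib, ic), (la, lb, lc)):
        nodes[idx].length = ln
    root = TreeNode(children=[nodes[ia], nodes[ib], nodes[ic]])
    return PhyloTree(root=root)


def _quote_label(name: str) -> str:
    if any(ch in name for ch in " ()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_node(node: TreeNode, with_length: bool) -> str:
    if node.is_leaf():
        s = _quote_label(node.name or "")
    else:
        s = "(" + ",".join(_newick_node(c, with_length) for c in node.children) + ")"
        if node.name:
            s += _quote_label(node.name)
    if with_length:
        s += f":{node.length:.6g}"
    return s


def to_newick(tree: PhyloTree) -> str:
    inner = ",".join(_newick_node(c, True) for c in tree.root.children)
    return f"({inner});"


def write_newick(tree: PhyloTree, path) -> None:
    """Serialize to Newick (branch lengths at 6 significant digits)."""
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


def tree_distances(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix implied by a tree.

    On an additive input matrix, NJ output run back through this function
    reproduces the input exactly, which is the strongest practical test of
    both topology and branch lengths.
    """
    labels = tree.leaf_names()
    index = {lbl: i for i, lbl in enumerate(labels)}
    n = len(labels)
    M = np.zeros((n, n))

    def collect(node: TreeNode) -> dict[str, float]:
        if node.is_leaf():
            return {node.name: node.length}
        child_maps = [collect(c) for c in node.children]
        for m1, m2 in itertools.combinations(child_maps, 2):
            for k1, d1 in m1.items():
                for k2, d2 in m2.items():
                    i, j = index[k1], index[k2]
                    M[i, j] = M[j, i] = d1 + d2
        merged: dict[str, float] = {}
        for cm in child_maps:
            for k, v in cm.items():
                merged[k] = v + node.length
        return merged

    collect(tree.root)
    return DistanceMatrix(labels, M)


def random_additive_tree(n_leaves: int, rng: np.random.Generator,
                         length_range: tuple[float, float] = (0.1, 5.0)
                         ) -> tuple[PhyloTree, DistanceMatrix]:
    """Random unrooted binary tree and its exact leaf-to-leaf distance matrix.

    The independent ground truth for NJ-consistency checks: NJ must invert
    these distances back to the generating topology and branch lengths.
    """
    if n_leaves < 3:
        raise ParameterError("need at least 3 leaves")
    labels = [f"L{i:02d}" for i in range(n_leaves)]
    lo, hi = length_range
    nodes = [TreeNode(name=lbl, length=float(rng.uniform(lo, hi))) for lbl in labels]
    pool = nodes[:]
    while len(pool) > 3:
        idx = sorted(rng.choice(len(pool), size=2, replace=False), reverse=True)
        a = pool.pop(idx[0])
        b = pool.pop(idx[1])
        parent = TreeNode(children=[a, b], length=float(rng.uniform(lo, hi)))
        pool.append(parent)
    root = TreeNode(children=pool)
    tree = PhyloTree(root=root)

    dist: dict[str, dict[str, float]] = {lbl: {} for lbl in labels}

    def collect(node: TreeNode) -> dict[str, float]:
        if node.is_leaf():
            return {node.name: node.length}
        child_maps = [collect(c) for c in node.children]
        for m1, m2 in itertools.combinations(child_maps, 2):
            for k1, d1 in m1.items():
                for k2, d2 in m2.items():
                    dist[k1][k2] = dist[k2][k1] = d1 + d2
        merged: dict[str, float] = {}
        for cm in child_maps:
            for k, v in cm.items():
                merged[k] = v + node.length
        return merged

    collect(root)
    M = np.zeros((n_leaves, n_leaves))
    for i, j in itertools.combinations(range(n_leaves), 2):
        M[i, j] = M[j, i] = dist[labels[i]][labels[j]]
    return tree, DistanceMatrix(labels, M)
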