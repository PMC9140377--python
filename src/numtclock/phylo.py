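"""Trees, pairwise distances, neighbor joining and branch-length fitting.

The joint NUMT/mtDNA tree that everything downstream consumes is built here:
model-corrected pairwise distances (p, Jukes-Cantor, Kimura two-parameter),
neighbor joining on the distance matrix, outgroup rooting, and ordinary (or
non-negative) least-squares re-estimation of branch lengths on a fixed
topology, which is the workhorse of the jackknife resampler.

Distances use pairwise deletion: a column is dropped for a pair when either
sequence has a gap or an ambiguity code there.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import dendropy
import numpy as np
from scipy.optimize import nnls

from .alignment import CodingAlignment, encode_sequence


class SaturationError(ValueError):
    """Observed differences exceed the model's invertible range."""


# ---------------------------------------------------------------------------
# tree container


class Node:
    __slots__ = ("name", "length", "children", "parent", "sequence")

    def __init__(self, name=None, length=None, children=None):
        self.name = name
        self.length = length
        self.children = list(children) if children else []
        self.parent = None
        self.sequence = None
        for c in self.children:
            c.parent = self

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.name!r} len={self.length}>"


class Phylogeny:
    """A rooted tree with branch lengths in substitutions/site.

    Invariants: one root, unique leaf labels, branch lengths (where set)
    non-negative. An unrooted tree is represented as a root with three
    children (the form neighbor joining returns).
    """

    def __init__(self, root: Node):
        self.root = root
        labels = self.leaf_names()
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")
        for node in self.preorder():
            if node.length is not None and node.length < -1e-12:
                raise ValueError(
                    f"negative branch length on {node.name!r}: {node.length}"
                )

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def postorder(self) -> list[Node]:
        return list(reversed(self._reverse_postorder()))

    def _reverse_postorder(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    # -- queries -----------------------------------------------------------
    def find(self, name: str) -> Node:
        for n in self.preorder():
            if n.name == name:
                return n
        raise KeyError(f"no node named {name!r}")

    def _as_node(self, ref) -> Node:
        return ref if isinstance(ref, Node) else self.find(ref)

    def mrca(self, refs: Iterable) -> Node:
        nodes = [self._as_node(r) for r in refs]
        if not nodes:
            raise ValueError("mrca of an empty set")
        paths = []
        for n in nodes:
            path = []
            while n is not None:
                path.append(n)
                n = n.parent
            paths.append(path[::-1])
        anc = None
        for level in zip(*paths):
            if all(x is level[0] for x in level):
                anc = level[0]
            else:
                break
        return anc

    def path_length(self, a, b) -> float:
        """Sum of branch lengths on the unique path between two nodes."""
        na, nb = self._as_node(a), self._as_node(b)
        anc = self.mrca([na, nb])
        total = 0.0
        for n in (na, nb):
            while n is not anc:
                total += n.length or 0.0
                n = n.parent
        return total

    def leafset(self, node: Node) -> frozenset[str]:
        stack, out = [node], []
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.name)
            stack.extend(n.children)
        return frozenset(out)

    def is_monophyletic(self, labels: Iterable[str]) -> bool:
        want = frozenset(labels)
        return self.leafset(self.mrca(sorted(want))) == want

    # -- editing -----------------------------------------------------------
    def copy(self) -> "Phylogeny":
        def clone(n: Node) -> Node:
            c = Node(n.name, n.length, [clone(ch) for ch in n.children])
            c.sequence = n.sequence
            return c

        return Phylogeny(clone(self.root))

    def assign_internal_names(self, prefix: str = "n") -> None:
        """Give unnamed internal nodes stable, unique names (preorder)."""
        taken = {n.name for n in self.preorder() if n.name}
        i = 0
        for n in self.preorder():
            if n.name is None:
                while f"{prefix}{i}" in taken:
                    i += 1
                n.name = f"{prefix}{i}"
                taken.add(n.name)

    def collapse_unary(self) -> tuple["Phylogeny", dict[str, list[str]]]:
        """Splice out internal nodes with a single child.

        Returns the collapsed tree and a map from each kept branch (child
        node name) to the chain of original branch names it absorbed,
        ordered root-ward to tip-ward.
        """
        t = self.copy()
        merged: dict[str, list[str]] = {}

        def walk(n: Node) -> Node:
            chain = [n]
            total = n.length
            while len(n.children) == 1:
                n = n.children[0]
                chain.append(n)
                if n.length is not None:
                    total = (total or 0.0) + n.length
            kept = n
            kept.length = total
            merged[str(kept.name)] = [str(c.name) for c in chain]
            kept.children = [walk(c) for c in kept.children]
            for c in kept.children:
                c.parent = kept
            return kept

        root = t.root
        while len(root.children) == 1:
            # a unary root is itself spliced away
            child = root.children[0]
            child.length = None
            child.parent = None
            root = child
        root.children = [walk(c) for c in root.children]
        for c in root.children:
            c.parent = root
        return Phylogeny(root), merged

    # -- serialisation -----------------------------------------------------
    def to_newick(self, lengths: bool = True, precision: int = 10) -> str:
        def fmt_label(name) -> str:
            if name is None:
                return ""
            s = str(name)
            if any(ch in s for ch in " \t()[]':;,"):
                return "'" + s.replace("'", "''") + "'"
            return s

        def fmt(n: Node) -> str:
            if n.is_leaf:
                core = fmt_label(n.name)
            else:
                core = (
                    "(" + ",".join(fmt(c) for c in n.children) + ")"
                    + fmt_label(n.name)
                )
            if lengths and n.length is not None:
                core += f":{n.length:.{precision}g}"
            return core

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            raise ValueError(f"unparsable Newick: {exc}") from exc

        def convert(dn) -> Node:
            name = dn.taxon.label if dn.taxon is not None else dn.label
            node = Node(name, dn.edge.length)
            for ch in dn.child_nodes():
                node.add(convert(ch))
            return node

        return cls(convert(dt.seed_node))


# ---------------------------------------------------------------------------
# rooting


def root_at_edge(t: Phylogeny, child_ref, dist_from_child: float) -> Phylogeny:
    """Re-root on the branch above ``child_ref``, that far above the child."""
    t = t.copy()
    child = t._as_node(child_ref)
    parent = child.parent
    if parent is None:
        raise ValueError("cannot root on the root's own (nonexistent) branch")
    pendant = child.length if child.length is not None else 0.0
    if not (0.0 <= dist_from_child <= pendant) and pendant > 0:
        raise ValueError("rooting point outside the branch")

    chain: list[Node] = []
    n = parent
    while n is not None:
        chain.append(n)
        n = n.parent
    lengths = [n.length for n in chain]

    parent.children = [c for c in parent.children if c is not child]
    for i in range(len(chain) - 1):
        up = chain[i + 1]
        up.children = [c for c in up.children if c is not chain[i]]
        chain[i].children.append(up)
        up.parent = chain[i]
        up.length = lengths[i]

    root = Node()
    root.children = [child, parent]
    child.parent = root
    parent.parent = root
    child.length = dist_from_child
    parent.length = pendant - dist_from_child

    _suppress_unary(root)
    return Phylogeny(root)


def _suppress_unary(root: Node) -> None:
    stack = [root]
    while stack:
        n = stack.pop()
        kept = []
        for c in n.children:
            while len(c.children) == 1:
                g = c.children[0]
                g.length = (g.length or 0.0) + (c.length or 0.0)
                g.parent = n
                c = g
            kept.append(c)
            stack.append(c)
        n.children = kept
        for c in kept:
            c.parent = n


def root_with_outgroup(t: Phylogeny, outgroup: str) -> Phylogeny:
    """Root at the midpoint of the outgroup's pendant branch."""
    node = t.find(outgroup)  # raises KeyError if missing
    if not node.is_leaf:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf")
    pendant = node.length if node.length is not None else 0.0
    return root_at_edge(t, outgroup, pendant / 2.0)


# ---------------------------------------------------------------------------
# distances


def _encoded(seq) -> np.ndarray:
    if isinstance(seq, str):
        return encode_sequence(seq)
    return np.asarray(seq, dtype=np.int8)


def _pair_counts(ea: np.ndarray, eb: np.ndarray) -> tuple[int, int, int]:
    """(comparable columns, transition diffs, transversion diffs)."""
    valid = (ea >= 0) & (eb >= 0)
    a, b = ea[valid], eb[valid]
    diff = a != b
    # with A=0, C=1, G=2, T=3 transitions (A<->G, C<->T) preserve parity
    ts = int(np.count_nonzero(diff & ((a & 1) == (b & 1))))
    return int(valid.sum()), ts, int(np.count_nonzero(diff)) - ts


def ml_distance(a, b, model: str = "jc") -> float:
    """Pairwise divergence (substitutions/site) under p, JC or K80.

    Columns with a gap or ambiguity in either sequence are excluded.
    Raises :class:`SaturationError` when the correction is undefined
    (p >= 0.75 under JC; non-positive log argument under K80).
    """
    ea, eb = _encoded(a), _encoded(b)
    if ea.shape != eb.shape:
        raise ValueError("sequences have different lengths")
    ncomp, ts, tv = _pair_counts(ea, eb)
    if ncomp == 0:
        raise ValueError("no comparable columns between the two sequences")
    return _distance_from_counts(ncomp, ts, tv, model)


def _distance_from_counts(ncomp: int, ts: int, tv: int, model: str) -> float:
    p = (ts + tv) / ncomp
    if model == "p":
        return p
    if model == "jc":
        if p >= 0.75:
            raise SaturationError(f"p = {p:.4f} >= 0.75: JC distance undefined")
        return -0.75 * math.log1p(-4.0 * p / 3.0)
    if model == "k80":
        P, Q = ts / ncomp, tv / ncomp
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        if w1 <= 0.0 or w2 <= 0.0:
            raise SaturationError(
                f"K80 log argument non-positive (P={P:.4f}, Q={Q:.4f})"
            )
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)
    raise ValueError(f"unknown distance model {model!r}")


def jc_distance_variance(p: float, n: int) -> float:
    """Sampling variance of the JC distance given raw mismatch fraction p."""
    return p * (1.0 - p) / (n * (1.0 - 4.0 * p / 3.0) ** 2)


def distance_matrix(
    aln: CodingAlignment | np.ndarray,
    model: str = "jc",
    labels: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    if isinstance(aln, CodingAlignment):
        M = aln.matrix()
        labels = list(aln.ids)
    else:
        M = np.asarray(aln, dtype=np.int8)
        labels = list(labels) if labels else [str(i) for i in range(len(M))]
    n = len(M)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = ml_distance(M[i], M[j], model)
    return D, labels


# ---------------------------------------------------------------------------
# neighbor joining


def build_nj_tree(D, labels: Sequence[str]) -> Phylogeny:
    """Classic neighbor joining; returns an unrooted (trifurcating) tree.

    Negative intermediate branch lengths are clamped to zero with the
    deficit shifted to the sister branch so the joined pair keeps its
    distance; exact on additive matrices.
    """
    D = np.array(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix contains NaN or infinite entries")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal is not zero")
    if len(set(labels)) != n:
        raise ValueError("duplicate labels")

    nodes: dict[int, Node] = {i: Node(lab) for i, lab in enumerate(labels)}
    active = list(range(n))
    Dw = {i: {j: D[i, j] for j in active if j != i} for i in active}
    next_id = n

    def clamp_pair(li: float, lj: float, dij: float) -> tuple[float, float]:
        if li < 0.0:
            return 0.0, dij
        if lj < 0.0:
            return dij, 0.0
        return li, lj

    while len(active) > 3:
        m = len(active)
        r = {i: sum(Dw[i][j] for j in active if j != i) for i in active}
        best, bq = None, math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * Dw[i][j] - r[i] - r[j]
                if q < bq - 1e-12:
                    bq, best = q, (i, j)
        i, j = best
        dij = Dw[i][j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj, dij)
        u = Node(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        Dw[next_id] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = max(0.0, 0.5 * (Dw[i][k] + Dw[j][k] - dij))
            Dw[next_id][k] = duk
            Dw[k][next_id] = duk
            del Dw[k][i], Dw[k][j]
        del Dw[i], Dw[j]
        nodes[next_id] = u
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    x, y, z = active
    lx = 0.5 * (Dw[x][y] + Dw[x][z] - Dw[y][z])
    ly = 0.5 * (Dw[x][y] + Dw[y][z] - Dw[x][z])
    lz = 0.5 * (Dw[x][z] + Dw[y][z] - Dw[x][y])
    root = Node(children=[nodes[x], nodes[y], nodes[z]])
    for node, ln in zip((nodes[x], nodes[y], nodes[z]), (lx, ly, lz)):
        node.length = max(0.0, ln)
    return Phylogeny(root)


# ---------------------------------------------------------------------------
# branch-length fitting on a fixed topology


class UnrootedEdges:
    """The unrooted edge set of a (possibly rooted) tree.

    When the root has exactly two children, their two branches form a single
    unrooted edge; a fitted length for it is split evenly between the two.
    Each edge is keyed by its leaf-set bipartition (the side away from the
    root).
    """

    def __init__(self, tree: Phylogeny):
        self.tree = tree
        self.edges: list[tuple[frozenset[str], tuple[Node, ...]]] = []
        root = tree.root
        merged: tuple[Node, ...] | None = None
        if len(root.children) == 2:
            merged = tuple(root.children)
        for node in tree.preorder():
            if node is root:
                continue
            if merged and node in merged:
                continue
            self.edges.append((tree.leafset(node), (node,)))
        if merged:
            self.edges.append((tree.leafset(merged[0]), merged))
        self._index = {side: k for k, (side, _) in enumerate(self.edges)}
        self._all_leaves = frozenset(tree.leaf_names())

    def __len__(self) -> int:
        return len(self.edges)

    def design_matrix(self, leaf_order: Sequence[str]) -> np.ndarray:
        pairs = [
            (i, j)
            for i in range(len(leaf_order))
            for j in range(i + 1, len(leaf_order))
        ]
        A = np.zeros((len(pairs), len(self.edges)))
        for e, (side, _) in enumerate(self.edges):
            inside = np.array([name in side for name in leaf_order])
            for row, (i, j) in enumerate(pairs):
                if inside[i] != inside[j]:
                    A[row, e] = 1.0
        return A

    def set_lengths(self, x: np.ndarray) -> None:
        for (_, nodes), v in zip(self.edges, x):
            share = float(v) / len(nodes)
            for node in nodes:
                node.length = share

    def lengths(self) -> np.ndarray:
        return np.array(
            [sum(n.length or 0.0 for n in nodes) for _, nodes in self.edges]
        )

    def index_of(self, side: Iterable[str]) -> int:
        side = frozenset(side)
        if side in self._index:
            return self._index[side]
        comp = self._all_leaves - side
        if comp in self._index:
            return self._index[comp]
        raise KeyError(f"no edge with bipartition {sorted(side)}")


def fit_branch_lengths(
    edges: UnrootedEdges,
    D: np.ndarray,
    leaf_order: Sequence[str],
    A: np.ndarray | None = None,
) -> np.ndarray:
    """Least-squares branch lengths (non-negative) for a fixed topology.

    Solves the path-length equations ``sum of edge lengths on path(i,j) =
    D[i,j]`` over all leaf pairs by non-negative least squares, writes the
    solution into the tree, and returns the fitted edge-length vector.
    """
    if A is None:
        A = edges.design_matrix(leaf_order)
    iu = np.triu_indices(len(leaf_order), k=1)
    b = np.asarray(D)[iu]
    x, _ = nnls(A, b)
    edges.set_lengths(x)
    return x
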