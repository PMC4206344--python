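"""Rooted phylogenies with branch lengths.

The central object is :class:`Phylogeny`, a compact array-backed rooted tree
(parent pointers, per-edge lengths, tip labels).  Newick reading is delegated
to dendropy; everything downstream — pruning, patristic distances, the
maximum-clade-credibility consensus — operates on the array representation,
which is what the per-cell diversity metrics and the permutation nulls need
to be fast.

Conventions
-----------
* Exactly one root; every non-root node carries a finite branch length >= 0
  (the length of the edge to its parent).  The root has no edge.
* Tip labels are unique, non-empty strings; internal labels are discarded.
* Trees are treated as rooted.  Newick explicitly tagged ``[&U]`` is
  rejected: every metric in this package (Faith PD in particular) is defined
  relative to the root.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "parse_newick_list",
    "write_newick",
    "tree_total_length",
    "prune_to_taxa",
    "patristic_distance",
    "mcc_tree",
]

#: branch lengths are serialized with this many significant digits and
#: compared with this absolute tolerance throughout the package
LENGTH_SIGNIFICANT_DIGITS = 10
LENGTH_ATOL = 1e-9


class NewickParseError(ValueError):
    """Malformed Newick input (message carries the offending position)."""


class TreeValidationError(ValueError):
    """Structurally invalid tree (duplicate tips, negative lengths, ...)."""


class Phylogeny:
    """Rooted tree with branch lengths, stored as parent-pointer arrays.

    Parameters
    ----------
    parent
        ``parent[i]`` is the parent node index of node ``i``; the root has
        parent ``-1``.  Parents must precede children is *not* required.
    length
        ``length[i]`` is the length of the edge above node ``i``;
        ``nan`` at the root.
    label
        ``label[i]`` is the tip label for leaf nodes, ``None`` for internal
        nodes.
    """

    __slots__ = ("parent", "length", "label", "_children", "_postorder", "_tip_index")

    def __init__(
        self,
        parent: Sequence[int],
        length: Sequence[float],
        label: Sequence[str | None],
        validate: bool = True,
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.label = list(label)
        self._children: list[list[int]] | None = None
        self._postorder: np.ndarray | None = None
        self._tip_index: dict[str, int] | None = None
        if validate:
            self._validate()

    # ------------------------------------------------------------------ #
    # structure
    # ------------------------------------------------------------------ #

    def _validate(self) -> None:
        n = len(self.parent)
        if not (n == len(self.length) == len(self.label)):
            raise TreeValidationError("parent/length/label arrays differ in size")
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise TreeValidationError(f"expected exactly one root, found {len(roots)}")
        # connectivity / acyclicity: walking up from any node must reach the
        # root in < n steps
        root = int(roots[0])
        for i in range(n):
            v, steps = i, 0
            while v != root:
                v = int(self.parent[v])
                steps += 1
                if v < 0 or v >= n or steps > n:
                    raise TreeValidationError("tree is not connected and acyclic")
        nonroot = self.parent != -1
        lengths = self.length[nonroot]
        if not np.all(np.isfinite(lengths)):
            raise TreeValidationError("every non-root node needs a finite branch length")
        if np.any(lengths < 0):
            raise TreeValidationError("negative branch length")
        tips = [self.label[i] for i in self.tips()]
        if any(t is None or t == "" for t in tips):
            raise TreeValidationError("every leaf needs a non-empty label")
        dupes = [t for t, c in Counter(tips).items() if c > 1]
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def children(self) -> list[list[int]]:
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[int(p)].append(i)
            self._children = ch
        return self._children

    def tips(self) -> list[int]:
        ch = self.children()
        return [i for i in range(self.n_nodes) if not ch[i]]

    @property
    def tip_labels(self) -> list[str]:
        return [self.label[i] for i in self.tips()]  # type: ignore[misc]

    def tip_index(self) -> dict[str, int]:
        """Map tip label -> node index."""
        if self._tip_index is None:
            self._tip_index = {self.label[i]: i for i in self.tips()}  # type: ignore[misc]
        return self._tip_index

    def postorder(self) -> np.ndarray:
        """Node indices, children always before parents."""
        if self._postorder is None:
            ch = self.children()
            order: list[int] = []
            stack = [(self.root, False)]
            while stack:
                v, expanded = stack.pop()
                if expanded:
                    order.append(v)
                else:
                    stack.append((v, True))
                    for c in reversed(ch[v]):
                        stack.append((c, False))
            self._postorder = np.asarray(order, dtype=np.int64)
        return self._postorder

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node (root = 0)."""
        d = np.zeros(self.n_nodes)
        for v in self.postorder()[::-1]:  # preorder
            p = int(self.parent[v])
            if p >= 0:
                d[v] = d[p] + self.length[v]
        return d

    def node_heights(self) -> np.ndarray:
        """Max path length from each node down to a descendant tip (tips = 0)."""
        h = np.zeros(self.n_nodes)
        ch = self.children()
        for v in self.postorder():
            if ch[v]:
                h[v] = max(h[c] + self.length[c] for c in ch[v])
        return h

    def clade_tipsets(self, min_size: int = 2) -> dict[int, frozenset[str]]:
        """Tip-label set below each internal node with >= ``min_size`` tips."""
        ch = self.children()
        below: list[set[str]] = [set() for _ in range(self.n_nodes)]
        for v in self.postorder():
            if not ch[v]:
                below[v] = {self.label[v]}  # type: ignore[arg-type]
            else:
                for c in ch[v]:
                    below[v] |= below[c]
        return {
            v: frozenset(below[v])
            for v in range(self.n_nodes)
            if ch[v] and len(below[v]) >= min_size
        }

    # ------------------------------------------------------------------ #
    # derived quantities
    # ------------------------------------------------------------------ #

    def total_length(self) -> float:
        nonroot = self.parent != -1
        return float(np.sum(self.length[nonroot]))

    def path_to_root(self, node: int) -> list[int]:
        """Nodes from ``node`` up to (and including) the root."""
        path = [node]
        while self.parent[path[-1]] != -1:
            path.append(int(self.parent[path[-1]]))
        return path

    def patristic_matrix(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Dense tip-by-tip patristic distance matrix.

        ``order`` fixes the row/column taxon order (default: tip order).
        """
        labels = list(order) if order is not None else self.tip_labels
        idx = self.tip_index()
        missing = [t for t in labels if t not in idx]
        if missing:
            raise KeyError(f"unknown tip labels: {sorted(missing)}")
        nodes = [idx[t] for t in labels]
        # ancestry matrix over non-root nodes: A[i, j] = node j on path
        # root->tip i (j's edge included)
        n = self.n_nodes
        A = np.zeros((len(nodes), n), dtype=bool)
        for r, v in enumerate(nodes):
            for u in self.path_to_root(v):
                if self.parent[u] != -1:
                    A[r, u] = True
        w = np.where(self.parent != -1, self.length, 0.0)
        shared = (A * w) @ A.T  # shared root-path length of each pair
        d = A @ w
        return d[:, None] + d[None, :] - 2.0 * shared

    def __eq__(self, other: object) -> bool:  # structural, label-set based
        if not isinstance(other, Phylogeny):
            return NotImplemented
        if sorted(self.tip_labels) != sorted(other.tip_labels):
            return False
        order = sorted(self.tip_labels)
        return bool(
            np.allclose(
                self.patristic_matrix(order), other.patristic_matrix(order), atol=LENGTH_ATOL
            )
            and math.isclose(self.total_length(), other.total_length(), abs_tol=LENGTH_ATOL)
        )

    def __hash__(self):  # pragma: no cover - mutable container semantics
        raise TypeError("Phylogeny is not hashable")

    def __repr__(self) -> str:
        return f"<Phylogeny with {len(self.tips())} tips, total length {self.total_length():g}>"


# ---------------------------------------------------------------------- #
# Newick I/O
# ---------------------------------------------------------------------- #


def _from_dendropy(dtree: "dendropy.Tree") -> Phylogeny:
    if dtree.is_rooted is False:
        raise TreeValidationError(
            "unrooted Newick input is rejected: all metrics here are root-dependent"
        )
    nodes = list(dtree.preorder_node_iter())
    ids = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    length = np.full(len(nodes), np.nan)
    label: list[str | None] = [None] * len(nodes)
    for nd in nodes:
        i = ids[id(nd)]
        if nd.parent_node is not None:
            parent[i] = ids[id(nd.parent_node)]
            if nd.edge.length is None:
                raise TreeValidationError("missing branch length on a non-root edge")
            length[i] = float(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is not None and nd.taxon.label:
                label[i] = nd.taxon.label
            elif nd.label:
                label[i] = nd.label
    return Phylogeny(parent, length, label)


def parse_newick(text: str) -> Phylogeny:
    """Parse a single rooted Newick tree with branch lengths.

    Raises :class:`NewickParseError` (with the character position dendropy
    reports) on malformed input and :class:`TreeValidationError` on
    structurally invalid trees (duplicate tips, missing lengths, unrooted
    tag).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            rooting="default-rooted",
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        pos = ""
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        if line is not None:
            pos = f" (line {line}, column {col})"
        raise NewickParseError(f"malformed Newick{pos}: {exc}") from exc
    return _from_dendropy(dtree)


def parse_newick_list(text: str) -> list[Phylogeny]:
    """Parse a multi-tree Newick document (one tree per ';')."""
    chunks = [c.strip() for c in text.split(";") if c.strip()]
    return [parse_newick(c + ";") for c in chunks]


def _fmt(x: float) -> str:
    return format(float(x), f".{LENGTH_SIGNIFICANT_DIGITS}g")


def write_newick(tree: Phylogeny) -> str:
    """Serialize to Newick with 10-significant-digit branch lengths."""
    ch = tree.children()

    def render(v: int) -> str:
        if not ch[v]:
            body = tree.label[v] or ""
        else:
            body = "(" + ",".join(render(c) for c in ch[v]) + ")"
        if tree.parent[v] != -1:
            body += f":{_fmt(tree.length[v])}"
        return body

    return render(tree.root) + ";"


# ---------------------------------------------------------------------- #
# basic operations
# ---------------------------------------------------------------------- #


def tree_total_length(tree: Phylogeny) -> float:
    """Sum of all branch lengths (equals Faith PD of the full tip set)."""
    return tree.total_length()


def patristic_distance(tree: Phylogeny, a: str, b: str) -> float:
    """Branch-length sum along the unique tip-to-tip path (0 iff a == b)."""
    idx = tree.tip_index()
    missing = [t for t in (a, b) if t not in idx]
    if missing:
        raise KeyError(f"unknown tip labels: {sorted(set(missing))}")
    if a == b:
        return 0.0
    d = tree.depths()
    u, v = idx[a], idx[b]
    anc_u = set(tree.path_to_root(u))
    w = v
    while w not in anc_u:
        w = int(tree.parent[w])
    return float(d[u] + d[v] - 2.0 * d[w])


def prune_to_taxa(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Restrict the tree to ``keep``, preserving patristic distances.

    Degree-2 chains created by the restriction are collapsed with their
    lengths summed.  The root is retained (with the chain below it summed
    into a single root edge) so that root-to-tip path lengths — and hence
    root-inclusive Faith PD — are preserved as well.
    """
    keep = list(dict.fromkeys(keep))
    if not keep:
        raise ValueError("keep must contain at least one tip label")
    idx = tree.tip_index()
    missing = [t for t in keep if t not in idx]
    if missing:
        raise KeyError(f"unknown tip labels: {sorted(missing)}")

    marked = np.zeros(tree.n_nodes, dtype=bool)
    for t in keep:
        for u in tree.path_to_root(idx[t]):
            marked[u] = True
    ch = tree.children()

    parent: list[int] = []
    length: list[float] = []
    label: list[str | None] = []

    def emit(p_new: int, v: int, extra: float) -> None:
        """Descend from marked node v, collapsing single-child chains."""
        kept_children = [c for c in ch[v] if marked[c]]
        while len(kept_children) == 1 and ch[v]:
            c = kept_children[0]
            extra += tree.length[c]
            v = c
            kept_children = [c2 for c2 in ch[v] if marked[c2]]
        i_new = len(parent)
        parent.append(p_new)
        length.append(extra)
        label.append(tree.label[v] if not ch[v] else None)
        for c in kept_children:
            emit(i_new, c, float(tree.length[c]))

    root = tree.root
    # root itself: collapse any chain directly below it into the root edge(s)
    parent.append(-1)
    length.append(math.nan)
    label.append(None)
    for c in ch[root]:
        if marked[c]:
            emit(0, c, float(tree.length[c]))
    return Phylogeny(parent, length, label)


# ---------------------------------------------------------------------- #
# maximum clade credibility consensus
# ---------------------------------------------------------------------- #


def mcc_tree(sample: Sequence[Phylogeny]) -> Phylogeny:
    """Maximum-clade-credibility tree with mean node heights.

    Scans a sample of trees on one tip set, scores each tree by the sum of
    log clade frequencies over its internal clades (>= 2 tips), and returns
    the best-scoring *sample* tree (ties: lowest index) with each internal
    node's height replaced by the mean height of the matching clade across
    the sample trees that contain it.  Heights are measured as the maximum
    path length from the node down to a tip.

    Branch lengths of the returned tree are the original lengths adjusted by
    the height shifts of the two incident clades; on an ultrametric sample
    this equals rebuilding the tree from the mean heights directly, and a
    sample of identical trees is returned unchanged.  Negative lengths that
    incompatible means can produce are clamped to 0.
    """
    trees = list(sample)
    if not trees:
        raise ValueError("empty tree sample")
    tipset = frozenset(trees[0].tip_labels)
    for k, t in enumerate(trees):
        if frozenset(t.tip_labels) != tipset:
            raise TreeValidationError(f"tree {k} has a different tip-label set")

    n = len(trees)
    clade_count: Counter[frozenset[str]] = Counter()
    clade_heights: dict[frozenset[str], list[float]] = {}
    per_tree: list[dict[int, frozenset[str]]] = []
    for t in trees:
        clades = t.clade_tipsets()
        per_tree.append(clades)
        h = t.node_heights()
        for v, cl in clades.items():
            clade_count[cl] += 1
            clade_heights.setdefault(cl, []).append(float(h[v]))

    best_k, best_score = 0, -math.inf
    for k, clades in enumerate(per_tree):
        score = sum(math.log(clade_count[cl] / n) for cl in clades.values())
        if score > best_score + 1e-12:
            best_k, best_score = k, score

    chosen = trees[best_k]
    clades = per_tree[best_k]
    old_h = chosen.node_heights()
    shift = np.zeros(chosen.n_nodes)
    for v, cl in clades.items():
        shift[v] = float(np.mean(clade_heights[cl])) - old_h[v]

    new_len = chosen.length.copy()
    for v in range(chosen.n_nodes):
        p = int(chosen.parent[v])
        if p >= 0:
            new_len[v] = max(0.0, chosen.length[v] + shift[p] - shift[v])
    return Phylogeny(chosen.parent.copy(), new_len, list(chosen.label))
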