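"""Rooted binary phylogenies stored as flat arrays, with Newick I/O.

A :class:`Phylo` keeps one row per node. Tips occupy indices
``0 .. n_tips - 1`` and carry the labels in :attr:`Phylo.tip_labels`;
internal nodes follow. Each node stores the index of its parent
(``-1`` for the root) and the length of the edge above it, in time
units. This layout makes the pruning recursions used by the likelihood
code a single array pass, and keeps simulated trees bit-reproducible.

Newick parsing and writing are delegated to :mod:`dendropy`; this module
only validates the structural contract (rooted, binary, branch lengths
present, unique tip labels) and converts to and from the array layout.
"""

from __future__ import annotations

import numpy as np
import dendropy

__all__ = [
    "Phylo",
    "PhyloError",
    "NewickParseError",
    "NonUltrametricError",
    "read_newick",
    "write_newick",
    "loads_newick",
    "dumps_newick",
    "rescale_height",
]


class PhyloError(ValueError):
    """Invalid tree structure or arguments."""


class NewickParseError(PhyloError):
    """Input could not be interpreted as a rooted binary tree with branch lengths."""


class NonUltrametricError(PhyloError):
    """An operation that requires equal root-to-tip path lengths was given a
    non-ultrametric tree."""


class Phylo:
    """A rooted binary phylogeny with branch lengths.

    Parameters
    ----------
    parent
        Integer array of length ``2 * n_tips - 1``; ``parent[v]`` is the index
        of the parent of node ``v``, or ``-1`` for the root.
    edge_length
        Float array of the same length; ``edge_length[v]`` is the length of
        the edge above node ``v`` (ignored/zero for the root).
    tip_labels
        Unique labels for tips ``0 .. n_tips - 1``.
    """

    __slots__ = ("parent", "edge_length", "tip_labels", "_cache")

    def __init__(self, parent, edge_length, tip_labels, validate: bool = True):
        self.parent = np.ascontiguousarray(parent, dtype=np.int64)
        self.edge_length = np.ascontiguousarray(edge_length, dtype=np.float64)
        self.tip_labels = tuple(str(lab) for lab in tip_labels)
        self._cache: dict = {}
        if validate:
            self._validate()

    # ------------------------------------------------------------------
    # structure
    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return int(self.parent.shape[0])

    @property
    def root(self) -> int:
        r = self._cache.get("root")
        if r is None:
            roots = np.flatnonzero(self.parent < 0)
            if roots.size != 1:
                raise PhyloError(f"tree must have exactly one root, found {roots.size}")
            r = int(roots[0])
            self._cache["root"] = r
        return r

    def _validate(self) -> None:
        n, m = self.n_tips, self.n_nodes
        if n < 2:
            raise PhyloError("a tree needs at least 2 tips")
        if m != 2 * n - 1:
            raise PhyloError(
                f"a rooted binary tree with {n} tips has {2 * n - 1} nodes, got {m}"
            )
        if self.edge_length.shape[0] != m:
            raise PhyloError("parent and edge_length arrays must have equal length")
        if len(set(self.tip_labels)) != n:
            raise PhyloError("tip labels must be unique")
        root = self.root
        if root < n:
            raise PhyloError("the root cannot be a tip")
        if not np.all(np.isfinite(self.edge_length)):
            raise PhyloError("edge lengths must be finite")
        lengths = self.edge_length.copy()
        lengths[root] = 0.0
        if np.any(lengths < 0):
            raise PhyloError("edge lengths must be nonnegative")
        counts = np.bincount(self.parent[self.parent >= 0], minlength=m)
        if np.any(counts[:n] != 0):
            raise PhyloError("tips cannot have children")
        bad = np.flatnonzero(counts[n:] != 2)
        if bad.size:
            v = int(bad[0]) + n
            raise PhyloError(
                f"internal node {v} has {int(counts[v])} children; trees must be binary"
            )
        if self.preorder().shape[0] != m:
            raise PhyloError("tree contains disconnected nodes or a cycle")

    def children(self) -> list[list[int]]:
        ch = self._cache.get("children")
        if ch is None:
            ch = [[] for _ in range(self.n_nodes)]
            for v in range(self.n_nodes):
                p = int(self.parent[v])
                if p >= 0:
                    ch[p].append(v)
            self._cache["children"] = ch
        return ch

    def preorder(self) -> np.ndarray:
        """Node indices in root-to-tip order (parents before children)."""
        pre = self._cache.get("preorder")
        if pre is None:
            ch = self.children()
            order = np.empty(self.n_nodes, dtype=np.int64)
            stack = [self.root]
            k = 0
            while stack:
                v = stack.pop()
                order[k] = v
                k += 1
                stack.extend(reversed(ch[v]))
                if k > self.n_nodes:  # cycle guard
                    break
            pre = order[:k]
            self._cache["preorder"] = pre
        return pre

    def bottomup(self) -> np.ndarray:
        """Node indices with every child before its parent; the root is last."""
        bu = self._cache.get("bottomup")
        if bu is None:
            bu = self.preorder()[::-1].copy()
            self._cache["bottomup"] = bu
        return bu

    # ------------------------------------------------------------------
    # metrics
    # ------------------------------------------------------------------
    def depths(self) -> np.ndarray:
        """Time from the root for every node."""
        d = self._cache.get("depths")
        if d is None:
            d = np.zeros(self.n_nodes)
            pre = self.preorder()
            par, elen = self.parent, self.edge_length
            for v in pre[1:]:
                d[v] = d[par[v]] + elen[v]
            self._cache["depths"] = d
        return d

    @property
    def height(self) -> float:
        """Maximum root-to-tip distance T."""
        return float(self.depths()[: self.n_tips].max())

    def is_ultrametric(self, rtol: float = 1e-9) -> bool:
        d = self.depths()[: self.n_tips]
        top = float(d.max())
        return (top - float(d.min())) <= rtol * max(top, np.finfo(float).tiny)

    def mrca_depths(self) -> np.ndarray:
        """n x n matrix of root-to-MRCA distances s_ij (diagonal: tip depths)."""
        n = self.n_tips
        d = self.depths()
        S = np.zeros((n, n))
        tipsets: dict[int, np.ndarray] = {
            i: np.array([i], dtype=np.int64) for i in range(n)
        }
        ch = self.children()
        for v in self.bottomup():
            if v < n:
                continue
            a, b = (tipsets.pop(c) for c in ch[v])
            S[np.ix_(a, b)] = d[v]
            S[np.ix_(b, a)] = d[v]
            tipsets[v] = np.concatenate([a, b])
        np.fill_diagonal(S, d[:n])
        return S

    # ------------------------------------------------------------------
    # transforms
    # ------------------------------------------------------------------
    def copy(self) -> "Phylo":
        return Phylo(self.parent.copy(), self.edge_length.copy(), self.tip_labels,
                     validate=False)

    def rescale(self, target_height: float) -> "Phylo":
        if target_height <= 0:
            raise PhyloError("target height must be positive")
        t = self.height
        if t <= 0:
            raise PhyloError("cannot rescale a zero-height tree")
        return Phylo(self.parent.copy(), self.edge_length * (target_height / t),
                     self.tip_labels, validate=False)

    # ------------------------------------------------------------------
    # dendropy / newick
    # ------------------------------------------------------------------
    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = []
        for v in range(self.n_nodes):
            node = dendropy.Node()
            if v < self.n_tips:
                node.taxon = taxa.new_taxon(label=self.tip_labels[v])
            node.edge.length = float(self.edge_length[v])
            nodes.append(node)
        for v in range(self.n_nodes):
            p = int(self.parent[v])
            if p >= 0:
                nodes[p].add_child(nodes[v])
        tree.seed_node = nodes[self.root]
        tree.seed_node.edge.length = None
        return tree

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylo":
        seed = dtree.seed_node
        # tolerate a unifurcating "rooting" node above the true root
        while len(seed.child_nodes()) == 1:
            seed = seed.child_nodes()[0]
        leaves, internals = [], []
        stack = [seed]
        while stack:
            node = stack.pop()
            kids = node.child_nodes()
            if not kids:
                leaves.append(node)
            else:
                if len(kids) != 2:
                    where = node.taxon.label if node.taxon else f"with {len(kids)} children"
                    raise NewickParseError(
                        f"non-binary node ({where}); only binary trees are supported"
                    )
                internals.append(node)
                stack.extend(reversed(kids))
        n = len(leaves)
        if n < 2:
            raise NewickParseError("tree must have at least 2 tips")
        labels = []
        for leaf in leaves:
            lab = leaf.taxon.label if leaf.taxon is not None else leaf.label
            if lab is None:
                raise NewickParseError("every tip must be labelled")
            labels.append(lab)
        if len(set(labels)) != n:
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickParseError(f"duplicate tip labels: {dup}")
        index = {id(leaf): i for i, leaf in enumerate(leaves)}
        index.update({id(node): n + j for j, node in enumerate(internals)})
        m = 2 * n - 1
        parent = np.full(m, -1, dtype=np.int64)
        elen = np.zeros(m)
        for node in leaves + internals:
            v = index[id(node)]
            if node is seed:
                continue
            parent[v] = index[id(node.parent_node)]
            if node.edge.length is None:
                where = node.taxon.label if node.taxon else "an internal node"
                raise NewickParseError(f"missing branch length above {where}")
            elen[v] = float(node.edge.length)
        return cls(parent, elen, labels)


def dumps_newick(tree: Phylo) -> str:
    """Serialize a tree as a one-line Newick string with branch lengths."""
    s = tree.to_dendropy().as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    )
    return s.strip()


def loads_newick(text: str) -> Phylo:
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    return Phylo.from_dendropy(dtree)


def read_newick(path) -> Phylo:
    """Read a rooted binary tree with branch lengths from a Newick file."""
    with open(path) as fh:
        return loads_newick(fh.read())


def write_newick(tree: Phylo, path) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_newick(tree) + "\n")


def rescale_height(tree: Phylo, target_height: float = 1.0) -> Phylo:
    """Return a copy with all edges multiplied so the height equals
    ``target_height``; topology is unchanged.

    Attraction strengths are read per unit tree height, so analyses in this
    package rescale to height 1 before fitting.
    """
    return tree.rescale(target_height)
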