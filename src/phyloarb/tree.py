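"""Rooted phylogenetic trees with re-rooting and split decomposition.

The tree is the substrate for every downstream computation: pruning
likelihoods for discrete traits, Brownian-motion covariances for
continuous traits, and bipartition (split) sets for topology comparison.
The convention throughout is that a branch length belongs to the edge
*above* (rootward of) a node, so the root carries no length.

Newick reading is delegated to dendropy; the in-memory structure is a
minimal parent/children graph because re-rooting at arbitrary internal
nodes — the primitive behind marginal ancestral state reconstruction —
needs explicit control over how the old root is suppressed.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping, Sequence

import dendropy

__all__ = ["Node", "Tree", "Split", "NewickError", "make_split"]

#: Branch lengths of exactly zero are clamped to this before any
#: likelihood computation; zero lengths make transition matrices and
#: phylogenetic covariances degenerate.
BRANCH_EPSILON = 1e-8

# A split is an unordered bipartition of the leaf set: a frozenset of two
# frozensets of leaf labels. Trivial splits (one block a singleton) are
# never produced by Tree.split_set().
Split = frozenset


class NewickError(ValueError):
    """Raised for malformed newick input."""


def make_split(block_a: Iterable[str], block_b: Iterable[str]) -> Split:
    a, b = frozenset(block_a), frozenset(block_b)
    if not a or not b or a & b:
        raise ValueError("split blocks must be disjoint and non-empty")
    return frozenset((a, b))


class Node:
    """A tree node. ``length`` is the length of the edge above the node
    (``None`` for the root). ``id`` is stable under copy/reroot/prune so
    ancestral-state results can be mapped back to the original tree."""

    __slots__ = ("label", "length", "parent", "children", "id")

    def __init__(self, label: str | None = None, length: float | None = None,
                 id: int | None = None):
        self.label = label
        self.length = length
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.id = id

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.id} {self.label!r} {kind} len={self.length}>"


class Tree:
    """Rooted tree with labelled leaves and non-negative branch lengths."""

    def __init__(self, root: Node):
        self.root = root
        self._assign_ids()
        labels = [lf.label for lf in self.leaves()]
        if any(lb is None for lb in labels):
            raise ValueError("every leaf must be labelled")
        if len(set(labels)) != len(labels):
            dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
            raise NewickError(f"duplicate leaf labels: {', '.join(dupes)}")
        for node in self.preorder():
            if node is not self.root and node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length {node.length} above {node.label or node.id}")

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse a newick string.

        Accepts quoted labels and underscores (kept verbatim), ignores
        internal-node support labels for all comparisons, and rejects
        unbalanced parentheses, duplicate leaves, and a missing terminal
        semicolon.
        """
        stripped = text.strip()
        if not stripped:
            raise NewickError("empty newick input")
        if not stripped.endswith(";"):
            raise NewickError(
                f"missing terminal semicolon (input ends at position {len(stripped)}: {stripped[-10:]!r})")
        depth = 0
        for pos, ch in enumerate(stripped):
            depth += ch == "("
            depth -= ch == ")"
            if depth < 0:
                raise NewickError(f"unbalanced ')' at position {pos}")
        if depth != 0:
            raise NewickError(f"unbalanced parentheses: {depth} '(' left open")
        try:
            dtree = dendropy.Tree.get(
                data=stripped, schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            raise NewickError(f"newick parse error: {exc}") from exc

        def convert(dnode) -> Node:
            if dnode.is_leaf():
                label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            else:
                label = dnode.label  # support values / internal names, kept but unused
            node = Node(label=label, length=dnode.edge.length)
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
            return node

        root = convert(dtree.seed_node)
        root.length = None
        return cls(root)

    @classmethod
    def from_file(cls, path) -> "Tree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        """Serialize with full-precision branch lengths (round-trip safe)."""

        def needs_quotes(label: str) -> bool:
            return any(c in label for c in "(),:;'[] \t\n")

        def fmt_label(label: str | None) -> str:
            if label is None:
                return ""
            if needs_quotes(label):
                return "'" + label.replace("'", "''") + "'"
            return label

        def fmt_len(node: Node) -> str:
            if node.length is None:
                return ""
            return f":{node.length!r}"

        def rec(node: Node) -> str:
            if node.is_leaf:
                return fmt_label(node.label) + fmt_len(node)
            inner = ",".join(rec(c) for c in node.children)
            return f"({inner})" + fmt_label(node.label if node is not self.root else None) + fmt_len(node)

        return rec(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------- traversal

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def find(self, label_or_id) -> Node:
        for node in self.preorder():
            if node.label == label_or_id or node.id == label_or_id:
                return node
        raise KeyError(f"node {label_or_id!r} not in tree")

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of a set of leaf labels."""
        want = set(labels)
        below: dict[int, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node.id] = {node.label}
            else:
                below[node.id] = set().union(*(below[c.id] for c in node.children))
            if want <= below[node.id]:
                return node
        raise KeyError(f"labels not all present: {sorted(want - set(self.leaf_labels()))}")

    # ------------------------------------------------------------ properties

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.preorder() if n is not self.root)

    def depths(self) -> dict[int, float]:
        """Root-to-node path lengths keyed by node id."""
        out = {self.root.id: 0.0}
        for node in self.preorder():
            if node is not self.root:
                out[node.id] = out[node.parent.id] + (node.length or 0.0)
        return out

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between every unordered pair of leaves."""
        depth = self.depths()
        # leaf sets and per-node accumulation of cross-pair distances
        dist: dict[tuple[str, str], float] = {}
        below: dict[int, list[Node]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node.id] = [node]
                continue
            kids = [below[c.id] for c in node.children]
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    for a in kids[i]:
                        for b in kids[j]:
                            key = (a.label, b.label) if a.label < b.label else (b.label, a.label)
                            dist[key] = depth[a.id] + depth[b.id] - 2 * depth[node.id]
            below[node.id] = [lf for k in kids for lf in k]
        return dist

    # ------------------------------------------------------------- structure

    def copy(self) -> "Tree":
        def rec(node: Node) -> Node:
            new = Node(node.label, node.length, id=node.id)
            for child in node.children:
                new.add_child(rec(child))
            return new
        return Tree(rec(self.root))

    def _assign_ids(self) -> None:
        next_id = max((n.id for n in self.preorder() if n.id is not None), default=-1) + 1
        for node in self.postorder():
            if node.id is None:
                node.id = next_id
                next_id += 1

    def clamped(self, eps: float = BRANCH_EPSILON) -> "Tree":
        """Copy with every branch length raised to at least ``eps``."""
        new = self.copy()
        for node in new.preorder():
            if node is not new.root:
                node.length = max(node.length or 0.0, eps)
        return new

    def reroot_at(self, node_ref) -> "Tree":
        """Re-root at an internal node, preserving the unrooted topology
        and all leaf-to-leaf path lengths.

        The old root, left with a single child after the parent chain is
        reversed, is suppressed (its two incident edges merged) — exactly
        the operation behind the re-rooting method for marginal ancestral
        states, where each internal node takes its turn as the root.
        """
        new = self.copy()
        target = new.find(node_ref if not isinstance(node_ref, Node) else node_ref.id)
        if target.is_leaf:
            raise ValueError(f"cannot reroot at leaf {target.label!r}")
        if target is new.root:
            return new
        # path from target up to old root
        chain: list[Node] = []
        cursor: Node | None = target
        while cursor is not None:
            chain.append(cursor)
            cursor = cursor.parent
        # reverse parent/child relations along the chain; the edge between
        # child and parent keeps its length but flips direction
        original_lengths = [n.length for n in chain]
        for child, par in zip(chain, chain[1:]):
            par.children.remove(child)
        for (child, par), edge_len in zip(zip(chain, chain[1:]), original_lengths):
            child.add_child(par)
            par.length = edge_len
        target.length = None
        target.parent = None
        old_root = chain[-1]
        if len(old_root.children) == 1:
            # suppress the degree-2 old root: merge its two incident edges
            only = old_root.children[0]
            grand = old_root.parent
            only.length = (only.length or 0.0) + (old_root.length or 0.0)
            grand.children[grand.children.index(old_root)] = only
            only.parent = grand
        return Tree(target)

    def prune_to(self, keep: Iterable[str]) -> "Tree":
        """Restrict to a leaf subset; unifurcations are suppressed with
        branch lengths summed, so all retained path lengths are exact."""
        keep = set(keep)
        missing = keep - set(self.leaf_labels())
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise ValueError("cannot prune to fewer than 2 leaves")
        new = self.copy()

        def rec(node: Node) -> Node | None:
            if node.is_leaf:
                return node if node.label in keep else None
            kept = [rec(c) for c in node.children]
            kept = [c for c in kept if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                child.length = (child.length or 0.0) + (node.length or 0.0)
                return child
            node.children = []
            for c in kept:
                node.add_child(c)
            return node

        root = rec(new.root)
        root.parent = None
        root.length = None
        return Tree(root)

    # ----------------------------------------------------------------- splits

    def clades(self) -> dict[int, frozenset[str]]:
        """Leaf set below each node, keyed by node id."""
        out: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                out[node.id] = frozenset((node.label,))
            else:
                out[node.id] = frozenset().union(*(out[c.id] for c in node.children))
        return out

    def split_set(self) -> set[Split]:
        """Non-trivial bipartitions of the unrooted version of the tree.

        One split per internal edge; the two edges meeting at the root
        induce the same bipartition and are deduplicated. For a fully
        binary unrooted tree on n >= 4 leaves the set has n - 3 elements.
        """
        all_leaves = frozenset(self.leaf_labels())
        n = len(all_leaves)
        if n < 4:
            return set()
        clades = self.clades()
        splits: set[Split] = set()
        for node in self.postorder():
            if node is self.root:
                continue
            block = clades[node.id]
            if 2 <= len(block) <= n - 2:
                splits.add(frozenset((block, all_leaves - block)))
        return splits

    def summary(self) -> dict:
        return {
            "n_leaves": self.n_leaves,
            "n_internal": len(self.internal_nodes()),
            "total_length": self.total_length(),
            "binary": self.is_binary(),
        }

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree n_leaves={self.n_leaves} total_length={self.total_length():.4g}>"
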