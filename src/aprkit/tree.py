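"""Rooted-storage phylogenetic trees.

The tree is always stored rooted (possibly with a trifurcating root,
the natural output of neighbor joining); analyses that are defined on
the unrooted tree treat the root as an ordinary internal vertex.
Newick parsing is done through dendropy; serialisation is local so the
dialect (support values as internal-node labels, branch lengths to 10
significant digits) is under our control.
"""

from __future__ import annotations

import io

import dendropy

__all__ = ["Node", "PhyloTree", "TreeError"]


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name=None, length=None, support=None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self):
        return f"<Node {self.name or '*'} len={self.length}>"


class PhyloTree:
    def __init__(self, root: Node):
        self.root = root
        root.parent = None

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        text = text.strip()
        if text.count("(") != text.count(")"):
            raise TreeError("unbalanced parentheses in Newick string")
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as e:  # dendropy raises several error types
            raise TreeError(f"cannot parse Newick: {e}") from None

        def convert(dnode) -> Node:
            if dnode.is_leaf():
                name = dnode.taxon.label if dnode.taxon is not None else dnode.label
                node = Node(name=name)
            else:
                node = Node()
                label = dnode.label
                if label is not None:
                    try:
                        node.support = float(label)
                    except ValueError:
                        node.name = label
            length = dnode.edge.length
            if length is not None:
                if length < 0:
                    raise TreeError(f"negative branch length {length}")
                node.length = float(length)
            for child in dnode.child_nodes():
                node.add(convert(child))
            return node

        tree = cls(convert(dt.seed_node))
        tree.root.length = None  # a root edge has no meaning here
        labels = tree.tip_labels()
        if len(set(labels)) != len(labels):
            dup = sorted({t for t in labels if labels.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        return tree

    # -- traversal ----------------------------------------------------

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def internals(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.name for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def has_branch_lengths(self) -> bool:
        return all(n.length is not None for n in self.preorder() if n is not self.root)

    # -- serialisation ------------------------------------------------

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if with_support and node.support is not None:
                    s += format(node.support, ".10g")
                elif node.name:
                    s += node.name
            if node.length is not None and node.parent is not None:
                s += ":" + format(node.length, ".10g")
            return s

        return fmt(self.root) + ";"

    def __repr__(self):
        return f"<PhyloTree {self.n_tips} tips>"

    # -- copies and canonical form ------------------------------------

    def copy(self) -> "PhyloTree":
        def dup(node: Node) -> Node:
            new = Node(node.name, node.length, node.support)
            for c in node.children:
                new.add(dup(c))
            return new

        return PhyloTree(dup(self.root))

    def min_tip(self, node: Node) -> str:
        if node.is_tip:
            return node.name
        return min(self.min_tip(c) for c in node.children)

    def canonicalize(self) -> "PhyloTree":
        """Sort children everywhere by smallest descendant tip label."""
        tree = self.copy()

        def rec(node: Node) -> str:
            if node.is_tip:
                return node.name
            keys = [(rec(c), c) for c in node.children]
            keys.sort(key=lambda kv: kv[0])
            node.children = [c for _, c in keys]
            return keys[0][0]

        rec(tree.root)
        return tree

    # -- bipartitions --------------------------------------------------

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions of the unrooted tree, each keyed by
        its canonical side (smaller tip set; ties by sorted labels)."""
        all_tips = frozenset(self.tip_labels())
        out = set()
        for node in self.preorder():
            if node is self.root or node.is_tip:
                continue
            side = frozenset(t.name for t in self._subtree_tips(node))
            other = all_tips - side
            if len(side) < 2 or len(other) < 2:
                continue
            out.add(self._canonical_side(side, other))
        return out

    @staticmethod
    def _canonical_side(a: frozenset, b: frozenset) -> frozenset:
        if (len(a), tuple(sorted(a))) <= (len(b), tuple(sorted(b))):
            return a
        return b

    def _subtree_tips(self, node: Node) -> list[Node]:
        stack, out = [node], []
        while stack:
            n = stack.pop()
            if n.is_tip:
                out.append(n)
            else:
                stack.extend(n.children)
        return out

    # -- rerooting -----------------------------------------------------

    def _adjacency(self):
        adj: dict[int, list[tuple[Node, float | None]]] = {}
        index: dict[int, Node] = {}
        for node in self.preorder():
            index[id(node)] = node
            adj.setdefault(id(node), [])
            for c in node.children:
                adj[id(node)].append((c, c.length))
                adj.setdefault(id(c), []).append((node, c.length))
        return adj, index

    def rerooted_at(self, target: Node) -> "PhyloTree":
        """Return a copy rooted at *target* (an internal node of self).

        The old root is suppressed if it becomes a degree-2 vertex, so
        the unrooted shape and total branch length are preserved.
        """
        if target.is_tip:
            raise TreeError("cannot root at a tip")
        adj, _ = self._adjacency()

        def build(node: Node, came_from: Node | None, length) -> Node:
            new = Node(node.name, length, node.support)
            for nbr, elen in adj[id(node)]:
                if came_from is not None and nbr is came_from:
                    continue
                new.add(build(nbr, node, elen))
            return new

        root = build(target, None, None)
        # suppress any degree-2 vertex created by removing the old root
        PhyloTree._suppress_unifurcations(root)
        return PhyloTree(root)

    @staticmethod
    def _suppress_unifurcations(root: Node) -> None:
        stack = list(root.children)
        while stack:
            node = stack.pop()
            while len(node.children) == 1 and not node.is_tip:
                child = node.children[0]
                child.length = (child.length or 0.0) + (node.length or 0.0)
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx] = child
                child.parent = parent
                node = child
            stack.extend(node.children)

    def unrooted(self) -> "PhyloTree":
        """Copy with any binary root collapsed into a trifurcation."""
        tree = self.copy()
        root = tree.root
        if len(root.children) != 2:
            return tree
        a, b = root.children
        keep, fold = (a, b) if not a.is_tip else (b, a)
        if keep.is_tip:
            raise TreeError("cannot unroot a 2-tip tree")
        fold.length = (fold.length or 0.0) + (keep.length or 0.0)
        new_root = Node(keep.name, None, keep.support)
        for c in keep.children:
            new_root.add(c)
        new_root.add(fold)
        return PhyloTree(new_root)

    # -- branch length bookkeeping ------------------------------------

    def total_branch_length(self) -> float:
        return sum(
            n.length or 0.0 for n in self.preorder() if n is not self.root
        )
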