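"""Rooted lineage trees.

The model's tree convention: the root has exactly one child (the progenitor
needs time to divide before the first observable split) and every other
internal node has exactly two children.  Polytomies are tolerated only when a
tree is used purely for metric evaluation.

Every edge is identified by its child node; each node carries a branch length
in mutation units (``delta``) and/or time units (``time``).  Newick reading
and writing goes through dendropy.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Sequence

import dendropy

from .data import ValidationError

_counter = itertools.count()


class Node:
    __slots__ = ("name", "parent", "children", "delta", "time")

    def __init__(self, name=None, delta=None, time=None):
        self.name = name if name is not None else f"_n{next(_counter)}"
        self.parent: "Node | None" = None
        self.children: list["Node"] = []
        self.delta = delta
        self.time = time

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"Node({self.name!r})"


class LineageTree:
    """A rooted tree with named leaves and per-edge lengths."""

    def __init__(self, root: Node):
        self.root = root

    # -- construction ----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "LineageTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )

        def convert(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = Node(name=label, time=dnode.edge.length)
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
            return node

        return cls(convert(dtree.seed_node))

    def to_newick(self, lengths: str = "time", digits: int = 10) -> str:
        """Serialize to Newick. ``lengths`` is 'time', 'delta', or 'none'."""

        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = "" if node.name.startswith("_n") else node.name
                s = f"({inner}){label}"
            if lengths != "none" and node.parent is not None:
                ln = node.time if lengths == "time" else node.delta
                if ln is not None:
                    s += f":{ln:.{digits}g}"
            return s

        return fmt(self.root) + ";"

    @classmethod
    def from_leaf_clades(cls, clades: Sequence["LineageTree | Node"]) -> "LineageTree":
        """Join subtrees under a fresh root (with the single-child convention)."""
        root = Node(name="root")
        top = root.add_child(Node())
        nodes = [c.root if isinstance(c, LineageTree) else c for c in clades]
        cur = top
        # chain clades into a binary caterpillar
        if len(nodes) == 1:
            top.add_child(nodes[0])
            return cls(root)
        for i, n in enumerate(nodes[:-2]):
            cur.add_child(n)
            cur = cur.add_child(Node())
        cur.add_child(nodes[-2])
        cur.add_child(nodes[-1])
        return cls(root)

    # -- traversal -------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def edges(self) -> list[tuple[Node, Node]]:
        return [(n.parent, n) for n in self.postorder() if n.parent is not None]

    def find(self, name: str) -> Node:
        for n in self.postorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- invariants ------------------------------------------------------
    def validate(self, binary: bool = True) -> None:
        if len(self.root.children) != 1:
            raise ValidationError(
                f"root must have exactly one child, has {len(self.root.children)}"
            )
        names = self.leaf_names
        if len(set(names)) != len(names):
            raise ValidationError("duplicate leaf names")
        if binary:
            for n in self.postorder():
                if n is self.root or n.is_leaf:
                    continue
                if len(n.children) != 2:
                    raise ValidationError(
                        f"internal node {n.name} has {len(n.children)} children"
                    )

    def check_ultrametric(self, height: float, attr: str = "delta", tol: float = 1e-6) -> None:
        for leaf in self.leaves():
            total, node = 0.0, leaf
            while node.parent is not None:
                total += getattr(node, attr)
                node = node.parent
            if abs(total - height) > tol:
                raise ValidationError(
                    f"leaf {leaf.name}: root path {attr} sum {total:.9g} != {height:.9g}"
                )

    # -- lengths ---------------------------------------------------------
    def set_deltas(self, delta: dict[str, float]) -> None:
        for node in self.postorder():
            if node.parent is not None:
                node.delta = delta[node.name]

    def delta_dict(self) -> dict[str, float]:
        return {n.name: n.delta for n in self.postorder() if n.parent is not None}

    def time_dict(self) -> dict[str, float]:
        return {n.name: n.time for n in self.postorder() if n.parent is not None}

    def times_from_deltas(self, lam: float) -> None:
        for node in self.postorder():
            if node.parent is not None and node.delta is not None:
                node.time = node.delta / lam

    def deltas_from_times(self, lam: float) -> None:
        for node in self.postorder():
            if node.parent is not None and node.time is not None:
                node.delta = lam * node.time

    def root_distances(self, attr: str = "delta") -> dict[str, float]:
        """Distance from the root to each node (bottom end of its edge)."""
        dist = {self.root.name: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                dist[node.name] = dist[node.parent.name] + (getattr(node, attr) or 0.0)
        return dist

    # -- copies and surgery ----------------------------------------------
    def copy(self) -> "LineageTree":
        def rec(node: Node) -> Node:
            clone = Node(name=node.name, delta=node.delta, time=node.time)
            for c in node.children:
                clone.add_child(rec(c))
            return clone

        return LineageTree(rec(self.root))

    def restrict(self, keep: Iterable[str]) -> "LineageTree":
        """Restrict to a leaf subset, suppressing unary nodes (lengths add)."""
        keep = set(keep)
        missing = keep - set(self.leaf_names)
        if missing:
            raise ValidationError(f"leaves not in tree: {sorted(missing)[:5]}")

        def rec(node: Node) -> Node | None:
            if node.is_leaf:
                if node.name in keep:
                    return Node(name=node.name, delta=node.delta, time=node.time)
                return None
            kept = [rec(c) for c in node.children]
            kept = [c for c in kept if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                # merge this edge into the surviving child's edge
                if node.parent is not None:
                    if child.delta is not None and node.delta is not None:
                        child.delta += node.delta
                    if child.time is not None and node.time is not None:
                        child.time += node.time
                return child
            clone = Node(name=node.name, delta=node.delta, time=node.time)
            for c in kept:
                clone.add_child(c)
            return clone

        new_root = Node(name=self.root.name)
        body = rec(self.root.children[0])
        if body is None:
            raise ValidationError("restriction removed every leaf")
        new_root.add_child(body)
        return LineageTree(new_root)


def topologies_equal(t1: LineageTree, t2: LineageTree) -> bool:
    """Rooted-topology equality on the shared leaf set."""

    def canon(node: Node):
        if node.is_leaf:
            return (node.name,)
        return tuple(sorted((canon(c) for c in node.children), key=repr))

    return canon(t1.root) == canon(t2.root)


def random_binary_tree(names: Sequence[str], rng) -> LineageTree:
    """Random rooted binary topology (single-child root) over ``names``."""
    nodes = [Node(name=n) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node(name="root")
    root.add_child(nodes[0])
    return LineageTree(root)
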