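"""Rooted binary trees, stratigraphic time-scaling, and pruning.

Trees are held in a small in-house node structure so that node ages (Ma) are
first-class; Newick/NEXUS reading and writing is delegated to dendropy.

Conventions
-----------
* Ages are in Ma (millions of years before present) and decrease toward the
  tips; branch durations are Myr.
* A leaf of a time-scaled tree sits at the first-appearance datum (FAD) of
  its taxon — minimum-age dating.  The last-appearance datum (LAD) is kept in
  the :class:`AgeTable` and only enters diversity-curve computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import dendropy

__all__ = [
    "Node",
    "Cladogram",
    "TimeTree",
    "TreeError",
    "parse_tree",
    "write_tree",
    "timescale_equal",
    "prune_taxa",
]


class TreeError(ValueError):
    """Raised for malformed trees (polytomies, duplicate labels, bad ages)."""


@dataclass
class Node:
    label: str | None = None
    age: float | None = None
    parent: "Node | None" = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out: list[Node] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]


class Cladogram:
    """A rooted, strictly binary tree with uniquely labelled leaves."""

    def __init__(self, root: Node):
        self.root = root
        self.validate()

    def validate(self) -> None:
        labels = []
        for node in self.root.preorder():
            if node.is_leaf:
                if not node.label:
                    raise TreeError("unlabelled leaf")
                labels.append(node.label)
            elif len(node.children) != 2:
                name = node.label or "{" + ",".join(
                    sorted(l.label for l in node.leaves())[:4]
                ) + "}"
                raise TreeError(
                    f"non-binary node {name}: {len(node.children)} children"
                )
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    def find_leaf(self, label: str) -> Node:
        for n in self.leaves():
            if n.label == label:
                return n
        raise KeyError(label)

    def copy(self) -> "Cladogram":
        return self.__class__(_copy_subtree(self.root))

    def mrca(self, labels) -> Node:
        """Most recent common ancestor of a set of leaf labels."""
        want = set(labels)
        for node in self.postorder():
            if not node.is_leaf:
                have = {l.label for l in node.leaves()}
                if want <= have:
                    return node
        raise KeyError(f"labels not all in tree: {sorted(want)}")


class TimeTree(Cladogram):
    """A Cladogram whose every node carries an age (Ma).

    Invariant: parent age strictly greater than child age (all branch
    durations positive).
    """

    def validate(self) -> None:
        super().validate()
        for node in self.root.preorder():
            if node.age is None:
                raise TreeError(f"node without age: {node.label}")
            for child in node.children:
                if child.age is None or not (node.age > child.age):
                    raise TreeError(
                        f"non-positive branch duration above "
                        f"{child.label or 'internal node'} "
                        f"({node.age} -> {child.age})"
                    )

    @property
    def root_age(self) -> float:
        return self.root.age

    def duration(self, node: Node) -> float:
        if node.parent is None:
            raise ValueError("root has no subtending branch")
        return node.parent.age - node.age


def _copy_subtree(node: Node) -> Node:
    new = Node(label=node.label, age=node.age)
    for child in node.children:
        new.add_child(_copy_subtree(child))
    return new


# ---------------------------------------------------------------------------
# Newick / NEXUS I/O (via dendropy)
# ---------------------------------------------------------------------------

def _from_dendropy(dnode: dendropy.Node) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    node = Node(label=label)
    for dchild in dnode.child_nodes():
        node.add_child(_from_dendropy(dchild))
    return node


def parse_tree(text: str, schema: str | None = None) -> Cladogram:
    """Parse a Newick or NEXUS string into a :class:`Cladogram`.

    The schema is sniffed when not given: anything starting with ``#NEXUS``
    is read as NEXUS, everything else as Newick.  The tree must be strictly
    binary; a polytomy raises :class:`TreeError` naming the offending node.
    """
    if schema is None:
        schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        dtree = dendropy.Tree.get(data=text, schema=schema)
    except Exception as exc:  # dendropy raises assorted parse errors
        raise TreeError(f"could not parse tree: {exc}") from None
    root = _from_dendropy(dtree.seed_node)
    # dendropy may attach a redundant unifurcation at the root
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
    return Cladogram(root)


def write_tree(tree: Cladogram, schema: str = "newick",
               branch_lengths: bool | None = None) -> str:
    """Serialise a tree to Newick (default) or NEXUS.

    For a :class:`TimeTree` branch lengths (durations, Myr) are written
    unless ``branch_lengths=False``.
    """
    if branch_lengths is None:
        branch_lengths = isinstance(tree, TimeTree)

    def fmt(node: Node) -> str:
        if node.is_leaf:
            s = node.label
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                s += node.label
        if branch_lengths and node.parent is not None:
            s += f":{node.parent.age - node.age:.10g}"
        return s

    newick = fmt(tree.root) + ";"
    if schema == "newick":
        return newick + "\n"
    if schema == "nexus":
        taxa = " ".join(tree.leaf_labels)
        return (
            "#NEXUS\nBEGIN TAXA;\n"
            f"    DIMENSIONS NTAX={len(tree.leaf_labels)};\n"
            f"    TAXLABELS {taxa};\nEND;\n"
            "BEGIN TREES;\n"
            f"    TREE tree1 = [&R] {newick}\nEND;\n"
        )
    raise ValueError(f"unknown schema: {schema}")


# ---------------------------------------------------------------------------
# Time-scaling: the "equal" method
# ---------------------------------------------------------------------------

def timescale_equal(clad: Cladogram, ages: Mapping[str, float] | "object",
                    root_extension: float) -> TimeTree:
    """Time-scale a cladogram from first-appearance dates, equal method.

    Steps:

    1. each leaf is placed at its FAD;
    2. each internal node at the maximum of its children's ages;
    3. the root is pushed back by ``root_extension`` (Myr);
    4. every chain of zero-duration branches is removed by re-spacing its
       nodes at equal intervals strictly between the nearest strictly older
       ancestor and the leaf that pinned the tied age.

    The re-spacing pass runs root-to-tips so windows opened upstream are
    available downstream; within a node, tied children are taken in child
    order.  ``ages`` is any mapping from leaf label to FAD, including an
    :class:`fossilrange.data.AgeTable`.
    """
    if root_extension <= 0:
        raise ValueError("root_extension must be > 0")
    fad = ages.fad if hasattr(ages, "fad") else dict(ages)
    tree = _copy_subtree(clad.root)

    missing = [l.label for l in tree.leaves() if l.label not in fad]
    if missing:
        raise TreeError(f"leaves without ages: {missing}")

    for node in Node.postorder(tree):
        if node.is_leaf:
            node.age = float(fad[node.label])
        else:
            node.age = max(c.age for c in node.children)
    tree.age += root_extension

    # Remove zero-duration chains by equal re-spacing (root-to-tips).  When
    # the first tie node.age == child.age is met in preorder, everything
    # above `node` is already strictly ordered, so the chain of tied nodes
    # starts at `node` and is anchored at node.parent.
    for node in Node.preorder(tree):
        for child in node.children:
            if child.age < node.age:
                continue
            if child.age > node.age:
                raise TreeError("child older than parent after initial pass")
            bottom_age = child.age
            if node.parent is None:
                raise TreeError(
                    "zero-duration branch at the root: increase root_extension"
                )
            chain = [node]
            cursor = node
            while True:
                nxt = next((c for c in cursor.children
                            if c.age == bottom_age and not c.is_leaf), None)
                if nxt is None:
                    break
                chain.append(nxt)
                cursor = nxt
            top_age = node.parent.age
            k = len(chain)
            for i, cnode in enumerate(chain, start=1):
                cnode.age = top_age - (top_age - bottom_age) * i / (k + 1)

    out = TimeTree(tree)  # validates positive durations
    return out


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def prune_taxa(tree: TimeTree, drop) -> TimeTree:
    """Remove a set of leaves; suppress the resulting degree-2 nodes.

    Node ages of retained nodes are unchanged, so durations across a
    suppressed node sum.  Raises if the drop set is not a strict subset of
    the leaf set or fewer than two leaves would remain.
    """
    drop = set(drop)
    labels = set(tree.leaf_labels)
    unknown = drop - labels
    if unknown:
        raise KeyError(f"taxa not in tree: {sorted(unknown)}")
    keep = labels - drop
    if len(keep) < 2:
        raise ValueError("pruning would leave fewer than 2 leaves")

    def build(node: Node) -> Node | None:
        if node.is_leaf:
            if node.label in drop:
                return None
            return Node(label=node.label, age=node.age)
        kids = [build(c) for c in node.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        new = Node(label=node.label, age=node.age)
        for k in kids:
            new.add_child(k)
        return new

    root = build(tree.root)
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
    return TimeTree(root)
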