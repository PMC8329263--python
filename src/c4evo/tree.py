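"""Rooted phylogenies with the node-numbering convention used throughout the package.

Internal nodes are labelled ``N1..Nm`` from the root, numbered in preorder so
that ancestors always receive lower numbers than their descendants and the
first ("A") clade is numbered before the second ("B") clade.  The
*preceding node* of an internal node is its nearest ancestral internal node;
by construction this is usually ``N(i-1)`` but clade boundaries introduce
exceptions (for the packaged Flaveria tree: N11→N5 and N10→N8), which are
carried as explicit map entries rather than re-derived from indices.

Newick I/O is delegated to :mod:`dendropy`; this module owns the in-memory
representation, numbering and ancestor queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "Node",
    "PhyloTree",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "number_nodes",
    "preceding_node",
    "mrca",
    "flaveria_tree",
    "FLAVERIA_NEWICK",
    "FLAVERIA_TIP_TYPES",
    "FLAVERIA_TIP_CLADES",
    "FLAVERIA_PRECEDING_OVERRIDES",
]

PHOTOSYNTHETIC_TYPES = ("C3", "C3-C4", "C4-like", "C4")


class NewickParseError(ValueError):
    """Raised for malformed newick input; carries the offending position."""


@dataclass
class Node:
    """A tree node.  ``label`` is the tip name for leaves, ``N<i>`` internally."""

    label: str | None = None
    length: float = 1.0
    parent: "Node | None" = None
    children: list["Node"] = field(default_factory=list)
    tip_type: str | None = None  # photosynthetic type, tips only

    @property
    def is_tip(self) -> bool:
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


class PhyloTree:
    """Rooted tree with unique tip labels and ``N``-numbered internal nodes."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> None:
        tips = [n.label for n in self.tips()]
        if len(tips) != len(set(tips)):
            raise ValueError("tip labels must be unique")
        internal = [n.label for n in self.internal_nodes() if n.label]
        if len(internal) != len(set(internal)):
            raise ValueError("internal labels must be unique")
        for node in self.root.preorder():
            if node is not self.root and node.length < 0:
                raise ValueError(f"negative branch length at {node.label!r}")

    # -- traversal -----------------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def tips(self) -> list[Node]:
        return [n for n in self.root.preorder() if n.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.root.preorder() if not n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def find(self, label: str) -> Node:
        for node in self.root.preorder():
            if node.label == label:
                return node
        raise KeyError(f"no node labelled {label!r}")

    # -- numbering and ancestry ----------------------------------------------------

    @property
    def n_internal(self) -> int:
        return len(self.internal_nodes())

    def preceding_map(self) -> dict[str, str]:
        """Map each non-root internal label to the label of its parent internal node."""
        out: dict[str, str] = {}
        for node in self.internal_nodes():
            if node.parent is not None and node.label and node.parent.label:
                out[node.label] = node.parent.label
        return out

    def preceding_overrides(self) -> dict[str, str]:
        """Entries of :meth:`preceding_map` that deviate from the default N(i-1) rule."""
        out = {}
        for label, pre in self.preceding_map().items():
            idx = _n_index(label)
            if idx is not None and pre != f"N{idx - 1}":
                out[label] = pre
        return out

    def mrca(self, tips: Iterable[str]) -> Node:
        labels = list(tips)
        if not labels:
            raise ValueError("mrca of an empty tip set is undefined")
        nodes = [self.find(lab) for lab in labels]
        paths = []
        for node in nodes:
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path[::-1])
        mrca_node = self.root
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                mrca_node = level[0]
            else:
                break
        return mrca_node

    # -- serialization -------------------------------------------------------------

    def to_newick(self) -> str:
        return write_newick(self)

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(label=node.label, length=node.length, tip_type=node.tip_type)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))


def _n_index(label: str) -> int | None:
    if label and label.startswith("N") and label[1:].isdigit():
        return int(label[1:])
    return None


# -- newick I/O --------------------------------------------------------------------


def parse_newick(text: str, default_length: float = 1.0) -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`.

    Missing branch lengths default to ``default_length``.  Internal node
    labels in the standard position (after the closing parenthesis) are kept.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several error types
        offset = getattr(exc, "col_num", None)
        where = f" near column {offset}" if offset is not None else ""
        raise NewickParseError(f"malformed newick{where}: {exc}") from exc

    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        length = dnode.edge.length if dnode.edge.length is not None else default_length
        node = Node(label=label, length=float(length))
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    return PhyloTree(convert(dtree.seed_node))


def write_newick(tree: PhyloTree) -> str:
    def fmt(node: Node) -> str:
        if node.is_tip:
            body = node.label or ""
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")" + (node.label or "")
        if node.parent is None:
            return body
        length = node.length
        ls = f"{length:g}"
        return f"{body}:{ls}"

    return fmt(tree.root) + ";"


# -- node numbering ----------------------------------------------------------------


def number_nodes(tree: PhyloTree, clade_order: list[str] | None = None) -> PhyloTree:
    """Assign internal labels N1..Nm in preorder, clade-A-first.

    ``clade_order`` is an ordered list of node labels (tips or existing
    internal labels) marking clade roots; at every internal node, child
    subtrees containing an earlier entry of ``clade_order`` are visited
    first.  Without ``clade_order`` the input child order is used.
    Relabelling an already numbered tree in the same order is a no-op.
    """
    tree = tree.copy()
    if clade_order:
        present = {n.label for n in tree.preorder() if n.label}
        missing = [lab for lab in clade_order if lab not in present]
        if missing:
            raise KeyError(f"clade_order references absent nodes: {missing}")
        priority = {lab: i for i, lab in enumerate(clade_order)}

        def subtree_priority(node: Node) -> int:
            best = len(clade_order)
            for sub in node.preorder():
                if sub.label in priority:
                    best = min(best, priority[sub.label])
            return best

        for node in tree.internal_nodes():
            node.children.sort(key=subtree_priority)

    counter = 0
    for node in tree.preorder():
        if not node.is_tip:
            counter += 1
            node.label = f"N{counter}"
    return PhyloTree(tree.root)


def preceding_node(label: str, overrides: dict[str, str] | None = None) -> str:
    """Nearest preceding (ancestral) internal node of ``label``.

    Defaults to ``N(i-1)``; ``overrides`` carries the clade-boundary
    exceptions (the packaged Flaveria tree has {N11: N5, N10: N8}).
    """
    if overrides and label in overrides:
        return overrides[label]
    idx = _n_index(label)
    if idx is None:
        raise KeyError(f"{label!r} is not an internal N-label")
    if idx == 1:
        raise ValueError("N1 is the root and has no preceding node")
    return f"N{idx - 1}"


def mrca(tree: PhyloTree, tips: Iterable[str]) -> str:
    """Label of the most recent common ancestor of ``tips``."""
    node = tree.mrca(tips)
    return node.label


# -- the packaged 16-species Flaveria topology -------------------------------------

#: Topology of the 16-species Flaveria tree used throughout: two basal C3
#: species, seven C3-C4 intermediates, three C4-like and four C4 species.
#: N7 is the common ancestor of the clade-A C4-like and C4 species; clade B
#: (N11..N14) attaches at N5.  Branch lengths default to 1.0 and are meant to
#: be overridden with real estimates via ``branch_lengths``.
FLAVERIA_NEWICK = (
    "(F_cronquistii:1,(F_robusta:1,(F_sonorensis:1,(F_angustifolia:1,"
    "((F_ramosissima:1,(F_palmeri:1,(F_vaginata:1,"
    "(F_bidentis:1,F_kochiana:1)N9:1,"
    "(F_trinervia:1,F_australasica:1)N10:1)N8:1)N7:1)N6:1,"
    "(F_anomala:1,(F_pubescens:1,(F_chloraefolia:1,"
    "(F_floridana:1,F_brownii:1)N14:1)N13:1)N12:1)N11:1)N5:1)N4:1)N3:1)N2:1)N1;"
)

FLAVERIA_TIP_TYPES: dict[str, str] = {
    "F_cronquistii": "C3",
    "F_robusta": "C3",
    "F_sonorensis": "C3-C4",
    "F_angustifolia": "C3-C4",
    "F_ramosissima": "C3-C4",
    "F_anomala": "C3-C4",
    "F_pubescens": "C3-C4",
    "F_chloraefolia": "C3-C4",
    "F_floridana": "C3-C4",
    "F_palmeri": "C4-like",
    "F_vaginata": "C4-like",
    "F_brownii": "C4-like",
    "F_bidentis": "C4",
    "F_kochiana": "C4",
    "F_trinervia": "C4",
    "F_australasica": "C4",
}

FLAVERIA_TIP_CLADES: dict[str, str] = {
    "F_cronquistii": "basal",
    "F_robusta": "basal",
    "F_sonorensis": "basal",
    "F_angustifolia": "A",
    "F_ramosissima": "A",
    "F_palmeri": "A",
    "F_vaginata": "A",
    "F_bidentis": "A",
    "F_kochiana": "A",
    "F_trinervia": "A",
    "F_australasica": "A",
    "F_anomala": "B",
    "F_pubescens": "B",
    "F_chloraefolia": "B",
    "F_floridana": "B",
    "F_brownii": "B",
}

#: Clade-boundary exceptions to the default N(i-1) preceding rule.
FLAVERIA_PRECEDING_OVERRIDES: dict[str, str] = {"N11": "N5", "N10": "N8"}


def flaveria_tree(branch_lengths: dict[str, float] | None = None) -> PhyloTree:
    """The packaged 16-tip Flaveria tree with photosynthetic-type metadata.

    ``branch_lengths`` maps node labels (tips or N-labels) to lengths,
    replacing the unit defaults on the branch leading into each node.
    """
    tree = parse_newick(FLAVERIA_NEWICK)
    for tip in tree.tips():
        tip.tip_type = FLAVERIA_TIP_TYPES[tip.label]
    if branch_lengths:
        for label, length in branch_lengths.items():
            node = tree.find(label)
            if length < 0:
                raise ValueError(f"negative branch length for {label!r}")
            node.length = float(length)
    return tree
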