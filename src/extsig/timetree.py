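"""Time-calibrated binary trees with extant and extinct tips.

The central container is :class:`TimeTree`, a rooted binary tree in which
every node carries two absolute times measured as ages before the present
(present = 0, past positive): ``birth`` (the age at which the lineage
segment begins, i.e. the parent's splitting age) and ``end`` (the age at
which it ends -- by splitting for internal nodes, by extinction or by
reaching the present for tips).  Edge lengths are ``birth - end``.

A "complete" tree may contain extinct tips (``end > 0``); a "reconstructed"
tree contains only extant tips.  :func:`drop_extinct` converts the former
into the latter; :func:`sample_tips` emulates incomplete taxon sampling.

Newick serialization is delegated to dendropy.
"""

from __future__ import annotations

import math
from typing import Callable, Iterator, Sequence

import dendropy
import numpy as np

TIME_TOL = 1e-9

__all__ = [
    "TIME_TOL",
    "TreeError",
    "CladeExtinctError",
    "UndersampledError",
    "Node",
    "TimeTree",
    "drop_extinct",
    "sample_tips",
    "read_newick",
    "write_newick",
]


class TreeError(ValueError):
    """Malformed or inconsistent tree."""


class CladeExtinctError(TreeError):
    """Fewer than two extant tips remain: the clade is effectively extinct."""


class UndersampledError(TreeError):
    """Tip sampling would leave fewer than two tips."""


class Node:
    """A lineage segment: from age ``birth`` down to age ``end``."""

    __slots__ = ("birth", "end", "children", "parent", "label")

    def __init__(self, birth: float, end: float, label: str | None = None):
        if end - birth > TIME_TOL:
            raise TreeError(f"negative edge length: birth={birth}, end={end}")
        self.birth = float(birth)
        self.end = float(end)
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.label = label

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def is_extant(self) -> bool:
        return self.is_tip and self.end <= TIME_TOL

    @property
    def edge_length(self) -> float:
        return self.birth - self.end

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else "internal"
        return f"<Node {self.label or ''} {kind} birth={self.birth:.4g} end={self.end:.4g}>"


class TimeTree:
    """Rooted, binary, time-calibrated tree.

    The root is the crown node: ``root.birth == root.end`` equals the crown
    age (the oldest split).
    """

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self.validate()

    # -- traversal ---------------------------------------------------------
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

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    def extant_tips(self) -> list[Node]:
        return [n for n in self.tips() if n.is_extant]

    def extinct_tips(self) -> list[Node]:
        return [n for n in self.tips() if not n.is_extant]

    # -- properties --------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tips())

    @property
    def n_extant(self) -> int:
        return len(self.extant_tips())

    @property
    def crown_age(self) -> float:
        return self.root.end

    @property
    def is_reconstructed(self) -> bool:
        return all(t.is_extant for t in self.tips())

    def total_branch_length(self) -> float:
        return sum(n.edge_length for n in self.preorder())

    # -- checks ------------------------------------------------------------
    def validate(self) -> None:
        if self.root.parent is not None:
            raise TreeError("root must have no parent")
        if abs(self.root.birth - self.root.end) > TIME_TOL:
            raise TreeError("root must have a zero-length edge (crown node)")
        for node in self.preorder():
            if node.children and len(node.children) != 2:
                raise TreeError("tree must be strictly binary")
            if node.end - node.birth > TIME_TOL:
                raise TreeError("edge lengths must be non-negative")
            for child in node.children:
                if abs(child.birth - node.end) > 1e-6:
                    raise TreeError(
                        "child birth time must equal parent end time "
                        f"({child.birth} != {node.end})"
                    )
            if node.end < -TIME_TOL:
                raise TreeError("node end time before the present")

    # -- manipulation ------------------------------------------------------
    def copy(self) -> "TimeTree":
        clones: dict[int, Node] = {}
        root_clone: Node | None = None
        for node in self.preorder():
            new = Node(node.birth, node.end, node.label)
            clones[id(node)] = new
            if node.parent is None:
                root_clone = new
            else:
                clones[id(node.parent)].add_child(new)
        assert root_clone is not None
        return TimeTree(root_clone, validate=False)

    def relabel_tips(self, prefix: str = "t") -> "TimeTree":
        for i, tip in enumerate(self.tips(), start=1):
            if tip.label is None:
                tip.label = f"{prefix}{i}"
        return self

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<TimeTree n_tips={self.n_tips} n_extant={self.n_extant} "
            f"crown_age={self.crown_age:.4g}>"
        )


# ---------------------------------------------------------------------------
# pruning operations
# ---------------------------------------------------------------------------

def _retain_tips(tree: TimeTree, keep: Callable[[Node], bool]) -> TimeTree:
    """Return a new tree containing only tips for which ``keep`` is true.

    Internal nodes left with a single child are suppressed (their edge
    lengths merge); the new root is the most recent common ancestor of the
    retained tips, re-expressed as a crown node.
    """

    pruned: dict[int, Node | None] = {}
    for node in tree.postorder():
        if node.is_tip:
            pruned[id(node)] = (
                Node(node.birth, node.end, node.label) if keep(node) else None
            )
            continue
        kept = [c for c in (pruned[id(ch)] for ch in node.children) if c is not None]
        if not kept:
            pruned[id(node)] = None
        elif len(kept) == 1:
            child = kept[0]
            child.birth = node.birth  # merge the suppressed edge
            pruned[id(node)] = child
        else:
            new = Node(node.birth, node.end)
            for c in kept:
                new.add_child(c)
            pruned[id(node)] = new

    new_root = pruned[id(tree.root)]
    if new_root is None or new_root.is_tip:
        raise CladeExtinctError("fewer than two tips retained")
    new_root.birth = new_root.end  # crown convention
    new_root.parent = None
    return TimeTree(new_root)


def drop_extinct(tree: TimeTree) -> TimeTree:
    """Prune all extinct tips, giving the reconstructed tree.

    Pairwise divergence times among extant tips are unchanged.  Raises
    :class:`CladeExtinctError` when fewer than two extant tips exist.
    """
    if tree.n_extant < 2:
        raise CladeExtinctError("clade extinct: fewer than 2 extant tips")
    return _retain_tips(tree, lambda n: n.is_extant)


def sample_tips(tree: TimeTree, fraction: float, rng: np.random.Generator) -> TimeTree:
    """Retain a uniformly random subset of ``ceil(fraction * n)`` tips.

    Emulates incomplete taxon sampling on a reconstructed tree.  Degree-2
    nodes arising from the pruning are suppressed as in :func:`drop_extinct`.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not tree.is_reconstructed:
        raise TreeError("sample_tips expects a reconstructed tree")
    tips = tree.tips()
    n_keep = math.ceil(fraction * len(tips))
    if n_keep < 2:
        raise UndersampledError(
            f"sampling {fraction:.0%} of {len(tips)} tips leaves fewer than 2"
        )
    if n_keep == len(tips):
        return tree.copy()
    idx = rng.choice(len(tips), size=n_keep, replace=False)
    chosen = {id(tips[i]) for i in idx}
    return _retain_tips(tree, lambda n: id(n) in chosen)


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------

def _to_dendropy(tree: TimeTree) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)
    counter = 0
    dnodes: dict[int, dendropy.Node] = {id(tree.root): dtree.seed_node}
    for node in tree.preorder():
        dnode = dnodes[id(node)]
        if node.is_tip:
            counter += 1
            dnode.taxon = taxa.new_taxon(label=node.label or f"t{counter}")
            continue
        for child in node.children:
            dnodes[id(child)] = dnode.new_child(edge_length=child.edge_length)
    dtree.seed_node.edge.length = None
    return dtree


def write_newick(tree: TimeTree, precision: int = 12) -> str:
    """Serialize to a one-line Newick string with branch lengths."""
    dtree = _to_dendropy(tree)
    s = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=f".{precision}g",
    )
    return s.strip()


def read_newick(text: str) -> TimeTree:
    """Parse a Newick string into a :class:`TimeTree`.

    Node times are recovered from branch lengths: the deepest tip defines
    the present; tips shallower than that are extinct, with positive end
    times.  Malformed input raises :class:`TreeError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"Newick parse error: {exc}") from exc

    # depth of each node from the seed node
    depth: dict[dendropy.Node, float] = {dtree.seed_node: 0.0}
    for dnode in dtree.preorder_node_iter():
        if dnode is dtree.seed_node:
            continue
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        depth[dnode] = depth[dnode.parent_node] + float(length)
    present = max(depth[leaf] for leaf in dtree.leaf_node_iter())

    children = dtree.seed_node.child_nodes()
    if len(children) != 2:
        raise TreeError("expected a rooted binary tree (root with 2 children)")

    nodes: dict[dendropy.Node, Node] = {}
    root: Node | None = None
    for dnode in dtree.preorder_node_iter():
        end = present - depth[dnode]
        if -1e-6 < end < 0:
            end = 0.0
        label = dnode.taxon.label if dnode.taxon is not None else None
        if dnode is dtree.seed_node:
            node = Node(end, end, label)
            root = node
        else:
            parent = nodes[dnode.parent_node]
            node = parent.add_child(Node(parent.end, end, label))
        nodes[dnode] = node
    assert root is not None
    return TimeTree(root)
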