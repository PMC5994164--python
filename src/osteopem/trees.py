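"""Rooted, time-calibrated phylogenies: Newick I/O, branch rounding, grafting.

Trees here are the substrate for phylogenetic eigenvector maps: rooted,
with branch lengths in Ma on every non-root edge.  Fossil taxa are added
to an extant backbone by grafting a pendant tip onto an existing edge at
a chosen time, which splits the edge in two and leaves every pre-existing
root-to-tip path length unchanged.

Newick parsing is delegated to :mod:`dendropy`; the canonical writer is a
small formatter of our own so that write-then-read is an exact identity.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from typing import Iterator

import dendropy

logger = logging.getLogger(__name__)

_ALNUM = re.compile(r"^[A-Za-z0-9_.\-]+$")


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be interpreted as a valid tree."""


class TreeStructureError(ValueError):
    """Raised when an operation would violate tree invariants."""


class Node:
    """A node of a rooted tree.

    Tips carry a label; every non-root node carries a branch length in Ma
    (the length of the edge to its parent).
    """

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else "node"
        return f"<{kind} {self.label!r} len={self.length}>"


@dataclass(frozen=True)
class GraftSpec:
    """Where and how to attach one new pendant tip.

    The attachment edge is identified by its *child* node label (a tip or a
    named internal node).  ``distance_from_child`` is measured from that
    child towards the root, in Ma; ``pendant_length`` is the new tip's own
    branch length in Ma (0 for a fossil that sits exactly on the edge).
    """

    label: str
    child: str
    distance_from_child: float
    pendant_length: float

    def __post_init__(self):
        if not self.label:
            raise ValueError("graft label must be non-empty")
        if self.pendant_length < 0:
            raise ValueError(f"pendant length must be >= 0, got {self.pendant_length}")
        if self.distance_from_child < 0:
            raise ValueError(
                f"attachment distance must be >= 0, got {self.distance_from_child}"
            )


class PhyloTree:
    """Rooted phylogeny with branch lengths in Ma.

    Invariants enforced at construction: a single root, unique non-empty tip
    labels, and a finite non-negative branch length on every non-root node.
    Trees need not be ultrametric — fossil tips end before the present.
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse a rooted Newick string with branch lengths on all non-root edges."""
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=False,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"malformed Newick: {exc}") from exc

        def convert(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = Node(label=label, length=dnode.edge.length)
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
            return node

        root = convert(dtree.seed_node)
        root.length = None  # any root edge length is dropped
        try:
            return cls(root)
        except TreeStructureError as exc:
            raise NewickParseError(str(exc)) from exc

    def to_newick(self, precision: int | None = 6) -> str:
        """Canonical Newick string.

        Labels are emitted unquoted when alphanumeric (plus ``_ . -``),
        quoted otherwise.  Branch lengths use up to ``precision`` significant
        digits; ``precision=None`` writes the shortest exact decimal
        representation so that write-then-read round-trips to the bit.
        """

        def fmt_label(label: str | None) -> str:
            if label is None:
                return ""
            if _ALNUM.match(label):
                return label
            return "'" + label.replace("'", "''") + "'"

        def fmt_len(x: float) -> str:
            if precision is None:
                return repr(float(x))
            s = f"{x:.{precision}g}"
            return s

        def emit(node: Node) -> str:
            if node.is_tip:
                core = fmt_label(node.label)
            else:
                core = "(" + ",".join(emit(c) for c in node.children) + ")" + fmt_label(
                    node.label
                )
            if node.length is not None:
                core += ":" + fmt_len(node.length)
            return core

        return emit(self.root) + ";"

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def write(self, path, precision: int | None = 6) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(precision=precision) + "\n")

    # ----------------------------------------------------------- traversal

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def edges(self) -> list[Node]:
        """Non-root nodes in preorder; each identifies the edge to its parent."""
        return [n for n in self.preorder() if not n.is_root]

    def n_tips(self) -> int:
        return len(self.tips())

    def find(self, label: str) -> Node:
        for node in self.preorder():
            if node.label == label:
                return node
        raise KeyError(f"no node labelled {label!r}")

    def mrca(self, labels: list[str]) -> Node:
        """Most recent common ancestor of the given tip labels."""
        paths = []
        for lab in labels:
            node = self.find(lab)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        anc = None
        for rank in zip(*paths):
            if all(n is rank[0] for n in rank):
                anc = rank[0]
            else:
                break
        return anc

    def depth(self, node: Node) -> float:
        """Root-to-node path length in Ma."""
        d = 0.0
        while node.parent is not None:
            d += node.length
            node = node.parent
        return d

    def tip_depths(self) -> dict[str, float]:
        return {t.label: self.depth(t) for t in self.tips()}

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(label=node.label, length=node.length)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return PhyloTree(clone(self.root))

    # --------------------------------------------------------- validation

    def _validate(self) -> None:
        if self.root.parent is not None:
            raise TreeStructureError("root must have no parent")
        seen: set[int] = set()
        labels: list[str] = []
        for node in self.preorder():
            if id(node) in seen:
                raise TreeStructureError("cycle detected in tree")
            seen.add(id(node))
            if node.is_root:
                continue
            if node.length is None:
                raise TreeStructureError(
                    f"missing branch length on edge to {node.label or 'internal node'!r}"
                )
            length = float(node.length)
            if not (length >= 0.0) or length != length or length == float("inf"):
                raise TreeStructureError(
                    f"branch length must be finite and >= 0, got {node.length!r} "
                    f"on edge to {node.label or 'internal node'!r}"
                )
            node.length = length
        for tip in self.tips():
            if not tip.label:
                raise TreeStructureError("every tip must carry a non-empty label")
            labels.append(tip.label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeStructureError(f"duplicate tip labels: {sorted(dupes)}")

    # -------------------------------------------------------- manipulation

    def round_branch_lengths(self) -> "PhyloTree":
        """Return a copy with every branch length rounded half-up to an integer Ma.

        Rounding can produce zero-length branches; these are retained (the
        PEM edge-weighting maps them to weight 0 for steepness < 1) and a
        warning is emitted for each.
        """
        import math

        new = self.copy()
        for node in new.preorder():
            if node.is_root:
                continue
            rounded = math.floor(node.length + 0.5)  # half-up on non-negative values
            if rounded == 0 and node.length > 0:
                msg = (
                    f"branch to {node.label or 'internal node'!r} rounded from "
                    f"{node.length} to 0 Ma"
                )
                warnings.warn(msg, stacklevel=2)
                logger.warning(msg)
            node.length = float(rounded)
        return new

    def graft_tips(self, grafts: list[GraftSpec]) -> "PhyloTree":
        """Attach pendant tips per the given specs, applied in list order.

        Each graft splits one edge at the requested distance from its child
        and hangs the new tip there, conserving all existing root-to-tip
        path lengths.
        """
        new = self.copy()
        for spec in grafts:
            existing = set(new.tip_labels())
            if spec.label in existing:
                raise TreeStructureError(f"duplicate new tip label {spec.label!r}")
            try:
                child = new.find(spec.child)
            except KeyError as exc:
                raise TreeStructureError(
                    f"unknown attachment edge (child {spec.child!r})"
                ) from exc
            if child.is_root:
                raise TreeStructureError("cannot graft onto the root (no parent edge)")
            if spec.distance_from_child > child.length:
                raise TreeStructureError(
                    f"attachment distance {spec.distance_from_child} exceeds edge "
                    f"length {child.length} (edge to {spec.child!r})"
                )
            parent = child.parent
            joint = Node(length=child.length - spec.distance_from_child)
            idx = parent.children.index(child)
            parent.children[idx] = joint
            joint.parent = parent
            child.length = spec.distance_from_child
            joint.add_child(child)
            joint.add_child(Node(label=spec.label, length=spec.pendant_length))
        return PhyloTree(new.root)

    def prune_tip(self, label: str) -> "PhyloTree":
        """Remove one tip; a resulting degree-two internal node is collapsed."""
        new = self.copy()
        tip = new.find(label)
        if not tip.is_tip:
            raise TreeStructureError(f"{label!r} is not a tip")
        parent = tip.parent
        if parent is None:
            raise TreeStructureError("cannot prune the only node")
        parent.children.remove(tip)
        if len(parent.children) == 1:
            only = parent.children[0]
            if parent.is_root:
                only.parent = None
                only.length = None
                return PhyloTree(only)
            only.length += parent.length
            grand = parent.parent
            idx = grand.children.index(parent)
            grand.children[idx] = only
            only.parent = grand
        return PhyloTree(new.root)
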