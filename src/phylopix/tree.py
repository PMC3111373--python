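"""Rooted multifurcating tree model and its assembly from line segments.

The segment graph of a rectangular phylogram maps onto a tree directly:
every vertical connector is an internal node, its children are the
horizontal branches leaving its right side ordered top-to-bottom, and its
parent is the horizontal branch arriving at its left side. Horizontal pixel
extent is the branch length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import MalformedJunctionError, NetworkError, RecognitionError
from .segments import Segment, SegmentSet, attach_map


@dataclass
class Node:
    """Tree node; a leaf iff ``children`` is empty."""

    branch_length: float = 0.0
    label: str | None = None
    children: list["Node"] = field(default_factory=list)
    attach_point: tuple[float, float] | None = None  # (x, y), tips only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        """Leaves in stored (top-to-bottom rendering) order."""
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def walk(self) -> list["Node"]:
        """All nodes, preorder."""
        out = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def n_leaves(self) -> int:
        return len(self.leaves())


@dataclass
class RecognizedTree:
    """Recognition output: rooted tree with pixel branch lengths."""

    root: Node
    #: length in px of the root stem (drawn from the left margin to the
    #: first connector); mirrored on ``root.branch_length``.
    root_length: float = 0.0

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def n_leaves(self) -> int:
        return self.root.n_leaves()

    def validate(self) -> list[str]:
        """Prerequisite violations; empty when the tree is well-formed."""
        violations = []
        seen: set[int] = set()
        for node in self.root.walk():
            if id(node) in seen:
                violations.append("network detected: node reachable twice")
                break
            seen.add(id(node))
            if not node.is_leaf and len(node.children) < 2:
                violations.append(
                    f"internal node with {len(node.children)} child(ren); "
                    "tree must be bi- or multifurcating"
                )
            if node.is_leaf and node.branch_length <= 0:
                violations.append("zero-length tip branch")
        if self.root.is_leaf:
            violations.append("single-leaf tree: no branching structure")
        return violations


def _segment_length(h: Segment, thickness: int, left_attached: bool) -> float:
    # Carving removed the connector columns from the branch's left end; add
    # them back so the length matches the drawn horizontal extent.
    return float(h.x_extent + (thickness if left_attached else 0))


def build_tree(segs: SegmentSet) -> RecognizedTree:
    """Assemble the rooted tree from the segment adjacency graph.

    Raises :class:`NetworkError` when the segment graph contains a cycle or
    a connector is claimed by two parent branches, and
    :class:`MalformedJunctionError` when a connector has fewer than two
    child branches.
    """
    horizontals = segs.horizontals
    verticals = segs.verticals
    if not horizontals:
        raise RecognitionError("no horizontal branches detected")
    left, right = attach_map(segs)
    thickness = segs.line_thickness

    children_of: dict[int, list[int]] = {j: [] for j in range(len(verticals))}
    parent_of: dict[int, int | None] = {}
    for i in range(len(horizontals)):
        if left[i] is not None:
            children_of[left[i]].append(i)
        if right[i] is not None:
            if right[i] in parent_of.values():
                raise NetworkError("not a tree: connector has two parent branches")
            parent_of[i] = right[i]

    used_h: set[int] = set()
    used_v: set[int] = set()

    def node_from_vertical(j: int, length: float) -> Node:
        if j in used_v:
            raise NetworkError("not a tree: connector reached twice")
        used_v.add(j)
        kids = sorted(children_of[j], key=lambda k: horizontals[k].y_center)
        if len(kids) < 2:
            raise MalformedJunctionError(
                f"connector at x={verticals[j].x0} joins {len(kids)} branch(es); "
                "expected at least 2"
            )
        return Node(
            branch_length=length,
            children=[node_from_horizontal(k) for k in kids],
        )

    def node_from_horizontal(i: int) -> Node:
        if i in used_h:
            raise NetworkError("not a tree: branch reached twice")
        used_h.add(i)
        h = horizontals[i]
        length = _segment_length(h, thickness, left[i] is not None)
        j = right[i]
        if j is None:
            return Node(
                branch_length=length,
                attach_point=(float(h.x1), h.y_center),
            )
        return node_from_vertical(j, length)

    roots = [i for i in range(len(horizontals)) if left[i] is None]
    if len(roots) > 1:
        raise RecognitionError(
            f"disconnected skeleton: {len(roots)} root candidates"
        )
    if roots:
        root = node_from_horizontal(roots[0])
    else:
        # No root stem drawn: the root is the leftmost connector that no
        # branch claims as its child junction.
        claimed = {j for j in right.values() if j is not None}
        free = [j for j in range(len(verticals)) if j not in claimed]
        if not free:
            raise NetworkError("not a tree: every connector has a parent branch")
        root_v = min(free, key=lambda j: verticals[j].x0)
        root = node_from_vertical(root_v, 0.0)
    if len(used_h) < len(horizontals):
        raise RecognitionError(
            f"disconnected skeleton: {len(horizontals) - len(used_h)} "
            "unreachable branch segment(s)"
        )
    if root.is_leaf:
        raise RecognitionError("single branch with no junctions; not a tree")
    return RecognizedTree(root=root, root_length=root.branch_length)
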