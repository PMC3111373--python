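"""Maximal horizontal/vertical line segments and tip detection.

A cleaned, thickness-normalized phylogram raster decomposes into horizontal
segments (branches) and vertical segments (connectors joining the children
of an internal node). A pixel counts toward a horizontal segment when its
horizontal run is long relative to the line thickness, and likewise for
vertical; junction pixels satisfy both and are assigned to the vertical so
that a parent branch and a collinear child branch are split at the
connector rather than fused across it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._runs import run_length_map
from .cleaning import EIGHT
from .errors import RecognitionError

#: Junction tolerance in px: a branch end "touches" a connector when their
#: bounding boxes, expanded by this much along the branch axis, overlap.
TOUCH_TOL = 1


@dataclass(frozen=True)
class Segment:
    """Maximal axis-aligned line segment, spans inclusive, in raster px."""

    orientation: str          # "horizontal" | "vertical"
    y0: int
    y1: int
    x0: int
    x1: int
    thickness: int

    @property
    def x_extent(self) -> int:
        return self.x1 - self.x0 + 1

    @property
    def y_extent(self) -> int:
        return self.y1 - self.y0 + 1

    @property
    def y_center(self) -> float:
        return (self.y0 + self.y1) / 2.0

    @property
    def x_center(self) -> float:
        return (self.x0 + self.x1) / 2.0


@dataclass(frozen=True)
class SegmentSet:
    horizontals: tuple[Segment, ...]
    verticals: tuple[Segment, ...]
    line_thickness: int


def _bbox_segments(mask: np.ndarray, orientation: str) -> list[Segment]:
    labels, n = ndimage.label(mask, structure=EIGHT)
    segs = []
    for sl in ndimage.find_objects(labels):
        if sl is None:
            continue
        ys, xs = sl
        thickness = (ys.stop - ys.start) if orientation == "horizontal" else (xs.stop - xs.start)
        segs.append(
            Segment(
                orientation=orientation,
                y0=ys.start,
                y1=ys.stop - 1,
                x0=xs.start,
                x1=xs.stop - 1,
                thickness=thickness,
            )
        )
    return segs


def extract_segments(mask: np.ndarray, thickness: int = 2) -> SegmentSet:
    """Decompose the skeleton into maximal horizontal and vertical segments.

    A run is "long" when it exceeds 4× the line thickness — short enough to
    catch every real branch and connector, long enough that speckle bumps
    welded onto a line by gap patching never masquerade as a segment.
    Long-horizontal pixels that also lie on a long vertical run belong to
    the vertical segment, which splits collinear branches at their shared
    connector.
    """
    mask = np.asarray(mask, dtype=bool)
    hlen = run_length_map(mask, axis=1)
    vlen = run_length_map(mask, axis=0)
    long_h = hlen > 4 * thickness
    long_v = vlen > 4 * thickness
    h_mask = long_h & ~long_v
    v_mask = long_v
    # A real branch spans well beyond one junction block; fragments shorter
    # than that are noise pixels that joined a long run at a junction row.
    min_extent = 2 * thickness + 1
    horizontals = [
        s for s in _bbox_segments(h_mask, "horizontal") if s.x_extent >= min_extent
    ]
    verticals = [
        s for s in _bbox_segments(v_mask, "vertical") if s.y_extent >= min_extent
    ]
    if not horizontals and not verticals:
        raise RecognitionError("no line segments detected")
    horizontals.sort(key=lambda s: (s.y0, s.x0))
    verticals.sort(key=lambda s: (s.x0, s.y0))
    return SegmentSet(
        horizontals=tuple(horizontals),
        verticals=tuple(verticals),
        line_thickness=thickness,
    )


def _touches(h: Segment, v: Segment, side: str, tol: int) -> bool:
    """Does horizontal ``h`` touch vertical ``v`` at its left or right end?"""
    if not (h.y1 >= v.y0 - 1 and h.y0 <= v.y1 + 1):
        return False
    if side == "left":
        return v.x1 >= h.x0 - tol - 1 and v.x0 <= h.x0 + tol
    return v.x0 <= h.x1 + tol + 1 and v.x1 >= h.x1 - tol


def attach_map(
    segs: SegmentSet, tol: int | None = None
) -> tuple[dict[int, int | None], dict[int, int | None]]:
    """For each horizontal segment index, the vertical index touching its
    left end (its parent connector) and its right end (its child connector),
    or None."""
    # Connector columns are carved out of the horizontal mask, so a branch
    # meeting a connector ends exactly one pixel short of it; the tolerance
    # only absorbs antialiasing erosion on top of that.
    tol = TOUCH_TOL if tol is None else tol
    left: dict[int, int | None] = {}
    right: dict[int, int | None] = {}
    for i, h in enumerate(segs.horizontals):
        left[i] = None
        right[i] = None
        for j, v in enumerate(segs.verticals):
            if left[i] is None and _touches(h, v, "left", tol):
                left[i] = j
            if right[i] is None and _touches(h, v, "right", tol):
                right[i] = j
    return left, right


def detect_tips(segs: SegmentSet) -> list[tuple[int, float]]:
    """Tip attach points: right ends of horizontals touching no vertical.

    Returns ``(x, y)`` points (y possibly fractional at even thickness),
    sorted by y ascending — the rendering order of the leaves.
    """
    _, right = attach_map(segs)
    tips = [
        (h.x1, h.y_center)
        for i, h in enumerate(segs.horizontals)
        if right[i] is None
    ]
    if not tips:
        raise RecognitionError("no leaves found")
    return sorted(tips, key=lambda p: p[1])
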