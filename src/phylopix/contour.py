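"""Moore-neighbor boundary tracing of foreground components.

Each 8-connected foreground component contributes one closed, clockwise
outer-boundary contour, started at its topmost-then-leftmost pixel and
terminated by Jacob's stopping criterion (re-entering the start pixel from
the original backtrack direction). Contours feed the diagnostic SVG overlay
and the boundary-accounting invariants of the recognizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cleaning import EIGHT
from .errors import RecognitionError

# Clockwise Moore neighborhood in (dx, dy), starting west, for an image with
# y increasing downward: W, NW, N, NE, E, SE, S, SW.
_NEIGHBORS = [(-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1)]


@dataclass(frozen=True)
class Contour:
    """Closed clockwise boundary: ordered (x, y) pixels of one component."""

    points: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.points)


def _trace_component(mask: np.ndarray, start: tuple[int, int]) -> Contour:
    h, w = mask.shape

    def fg(x: int, y: int) -> bool:
        return 0 <= x < w and 0 <= y < h and mask[y, x]

    sx, sy = start
    points: list[tuple[int, int]] = [(sx, sy)]
    cur = (sx, sy)
    # The start is the topmost-then-leftmost pixel, so its west neighbor is
    # background: begin the clockwise scan just after west.
    backtrack_dir = 0
    first_move: tuple[int, int, int] | None = None
    for _ in range(4 * mask.size + 8):
        found = None
        for k in range(1, 9):
            d = (backtrack_dir + k) % 8
            dx, dy = _NEIGHBORS[d]
            nx, ny = cur[0] + dx, cur[1] + dy
            if fg(nx, ny):
                found = (nx, ny, d)
                break
        if found is None:
            break  # isolated single pixel
        # Jacob's stopping criterion: stop when the trace is back at the
        # start and about to repeat its very first move.
        if cur == (sx, sy):
            if first_move is not None and found == first_move:
                break
            if first_move is None:
                first_move = found
        nx, ny, d = found
        if (nx, ny) != (sx, sy):
            points.append((nx, ny))
        cur = (nx, ny)
        backtrack_dir = (d + 4) % 8  # came-from direction
    return Contour(points=tuple(points))


def trace_contours(mask: np.ndarray) -> list[Contour]:
    """One outer-boundary contour per 8-connected foreground component."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=EIGHT)
    if n == 0:
        raise RecognitionError("no foreground to trace")
    contours = []
    order = []
    for i, sl in enumerate(ndimage.find_objects(labels), start=1):
        comp = labels[sl] == i
        ys, xs = np.nonzero(comp)
        k = np.lexsort((xs, ys))[0]  # topmost, then leftmost
        start = (int(xs[k] + sl[1].start), int(ys[k] + sl[0].start))
        order.append((start[1], start[0], i, start))
    for _, _, i, start in sorted(order):
        contours.append(_trace_component(labels == i, start))
    return contours


def boundary_pixel_count(mask: np.ndarray) -> int:
    """Number of foreground pixels with at least one background 4-neighbor."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return int((mask & ~interior).sum())
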