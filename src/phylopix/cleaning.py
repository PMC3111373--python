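"""Raster cleaning: speckle and glyph removal, line and corner patching.

The cleaning chain prepares a binarized, thickness-normalized raster for
segment extraction. Order matters: deletions run before bridging so patching
never welds noise into the tree.

    despeckle -> remove_unattached_horizontals -> remove_nonmain_components
              -> patch_lines_and_corners

All tolerances are expressed in rescaled units where lines are ~2 px thick.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._runs import gaps_1d, run_length_map, runs_1d
from .errors import RecognitionError

#: 8-connectivity structuring element used for all component labeling.
EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class CleaningConfig:
    """Tolerances of the cleaning chain, in rescaled (2-px-thick-line) pixels."""

    speckle_box: int = 4
    min_horizontal_len: int = 6
    max_gap: int = 3
    keep_largest_component: bool = True
    line_thickness: int = 2

    def __post_init__(self) -> None:
        if self.speckle_box < 1 or self.min_horizontal_len < 1 or self.max_gap < 0:
            raise ValueError("invalid cleaning tolerances")


@dataclass
class CleaningReport:
    speckles_removed: int = 0
    horizontals_removed: int = 0
    components_removed: int = 0
    gaps_patched: int = 0
    corners_patched: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def despeckle(mask: np.ndarray, speckle_box: int = 4) -> tuple[np.ndarray, int]:
    """Delete small blobs fully surrounded by background.

    A blob is a speckle when its bounding box fits in ``speckle_box`` ×
    ``speckle_box`` pixels and the one-pixel ring around that box is entirely
    background (pixels outside the image count as background).
    """
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    labels, n = ndimage.label(mask, structure=EIGHT)
    removed = 0
    for i, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        ys, xs = sl
        if ys.stop - ys.start > speckle_box or xs.stop - xs.start > speckle_box:
            continue
        y0 = max(ys.start - 1, 0)
        y1 = min(ys.stop + 1, mask.shape[0])
        x0 = max(xs.start - 1, 0)
        x1 = min(xs.stop + 1, mask.shape[1])
        window = mask[y0:y1, x0:x1]
        blob = labels[y0:y1, x0:x1] == i
        if (window & ~blob).any():   # ring contains other foreground
            continue
        seg = out[y0:y1, x0:x1]
        seg[blob] = False
        removed += 1
    return out, removed


def _vertical_structure(mask: np.ndarray, line_thickness: int) -> np.ndarray:
    """Pixels belonging to vertical runs at least twice the line thickness."""
    return run_length_map(mask, axis=0) >= 2 * line_thickness


def _bridge_gaps(mask: np.ndarray, max_gap: int) -> np.ndarray:
    """Row- and column-wise fill of flanked background gaps ≤ ``max_gap``."""
    out = mask.copy()
    for y in range(mask.shape[0]):
        for g0, g1 in gaps_1d(mask[y], max_gap):
            out[y, g0:g1] = True
    for x in range(mask.shape[1]):
        for g0, g1 in gaps_1d(mask[:, x], max_gap):
            out[g0:g1, x] = True
    return out


def remove_unattached_horizontals(
    mask: np.ndarray, cfg: CleaningConfig
) -> tuple[np.ndarray, int]:
    """Delete horizontal runs not anchored to any vertical line.

    Removes residual glyph strokes, underscores and dash fragments: a maximal
    horizontal run is kept when it touches (8-adjacency) a vertical run of
    length ≥ 2× line thickness; otherwise it is deleted if it is shorter than
    ``min_horizontal_len`` or its connected component contains no such
    vertical run at all. Connectivity is judged on a virtually gap-bridged
    copy of the raster, so a branch piece that later patching will reattach
    (it lies within ``max_gap`` of the tree) is never thrown away, while a
    lone dash far from everything still is.
    """
    mask = np.asarray(mask, dtype=bool)
    vert = _vertical_structure(mask, cfg.line_thickness)
    near_vert = ndimage.binary_dilation(vert, structure=EIGHT)
    bridged = _bridge_gaps(mask, cfg.max_gap)
    labels, _ = ndimage.label(bridged, structure=EIGHT)
    comp_ids_with_vert = set(np.unique(labels[vert]).tolist()) - {0}
    out = mask.copy()
    for y in range(mask.shape[0]):
        for x0, x1 in runs_1d(mask[y]):
            if near_vert[y, x0:x1].any():
                continue
            length = x1 - x0
            if length < cfg.min_horizontal_len or labels[y, x0] not in comp_ids_with_vert:
                out[y, x0:x1] = False
    _, removed = ndimage.label(mask & ~out, structure=EIGHT)
    return out, int(removed)


def remove_nonmain_components(
    mask: np.ndarray, cfg: CleaningConfig
) -> tuple[np.ndarray, int]:
    """Keep only the largest 8-connected component (the tree itself).

    Strips internal node-support numerals, scale bars and stray marks that do
    not touch the tree. Size ties break toward the leftmost-topmost bounding
    box. Connectivity is judged on a virtually gap-bridged raster, so a
    subtree severed from the tree by a small line break (which patching will
    repair) still counts as part of the main component.
    """
    mask = np.asarray(mask, dtype=bool)
    bridged = _bridge_gaps(mask, cfg.max_gap)
    labels, n = ndimage.label(bridged, structure=EIGHT)
    if n == 0 or not mask.any():
        raise RecognitionError("no foreground components")
    if not cfg.keep_largest_component or n == 1:
        return mask.copy(), 0
    sizes = np.bincount((labels * mask).ravel())[1:]  # sizes of real pixels
    best_size = sizes.max()
    candidates = np.flatnonzero(sizes == best_size) + 1
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        slices = ndimage.find_objects(labels)
        keep = min(
            candidates,
            key=lambda i: (slices[i - 1][1].start, slices[i - 1][0].start),
        )
    out = mask & (labels == keep)
    real_labels, n_real = ndimage.label(mask, structure=EIGHT)
    kept_ids = np.unique(real_labels[out])
    removed = n_real - (len(kept_ids) - (1 if 0 in kept_ids else 0))
    return out, int(removed)


def patch_lines_and_corners(
    mask: np.ndarray, cfg: CleaningConfig
) -> tuple[np.ndarray, CleaningReport]:
    """Bridge small line breaks and fill eroded corner blocks.

    Collinear run pairs separated by ≤ ``max_gap`` background pixels are
    bridged row-wise and column-wise; remaining concave corner notches at
    horizontal/vertical near-junctions are filled by a morphological closing
    with a ``max_gap`` × ``max_gap`` box. Only background→foreground flips
    occur.
    """
    mask = np.asarray(mask, dtype=bool)
    gap_fill = _bridge_gaps(mask, cfg.max_gap) & ~mask
    _, n_gaps = ndimage.label(gap_fill, structure=EIGHT)
    out = mask | gap_fill

    report = CleaningReport(gaps_patched=int(n_gaps))
    if cfg.max_gap >= 2:
        se = np.ones((cfg.max_gap, cfg.max_gap), dtype=bool)
        pad = cfg.max_gap
        padded = np.pad(out, pad, constant_values=False)
        closed = ndimage.binary_closing(padded, structure=se)[pad:-pad, pad:-pad]
        corner_fill = closed & ~out
        _, n_corners = ndimage.label(corner_fill, structure=EIGHT)
        report.corners_patched = int(n_corners)
        out |= corner_fill
    return out, report


def clean(
    mask: np.ndarray, cfg: CleaningConfig | None = None
) -> tuple[np.ndarray, CleaningReport]:
    """Run the full cleaning chain and aggregate the per-stage counts."""
    cfg = cfg or CleaningConfig()
    out, speckles = despeckle(mask, cfg.speckle_box)
    out, horizontals = remove_unattached_horizontals(out, cfg)
    out, components = remove_nonmain_components(out, cfg)
    out, patch_report = patch_lines_and_corners(out, cfg)
    patch_report.speckles_removed = speckles
    patch_report.horizontals_removed = horizontals
    patch_report.components_removed = components
    return out, patch_report
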