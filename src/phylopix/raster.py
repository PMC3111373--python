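"""Image decoding, binarization and line-thickness normalization.

A recognizable phylogram is a dark drawing on a light background. This module
turns an arbitrary PNG/JPEG/GIF into a boolean foreground raster and rescales
it so horizontal branch lines are on average 2 pixels thick — every later
tolerance (speckle box, patchable gap, segment thresholds) is expressed in
those normalized units.

Coordinate convention throughout the package: arrays are indexed
``[row, col]``; reported points are ``(x, y)`` with x = column increasing
rightward and y = row increasing downward, origin at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.filters import threshold_otsu

from ._runs import run_length_map
from .errors import InputFormatError, ParameterError, RecognitionError

TARGET_THICKNESS = 2
#: Minimum horizontal run length (px) for a run to count as a line when
#: measuring thickness; excludes vertical connectors and text glyph strokes.
DEFAULT_MIN_RUN = 15

_SUPPORTED_FORMATS = {"PNG", "JPEG", "GIF"}


@dataclass(frozen=True)
class ScaleReport:
    """Record of the thickness-normalizing rescale.

    ``scale_factor`` maps original-image coordinates to rescaled ones
    (rescaled = original × scale_factor); its inverse maps recognized
    geometry back onto the original image for label cropping and the SVG
    overlay.
    """

    measured_thickness: float
    scale_factor: float
    target_thickness: int = TARGET_THICKNESS

    def to_original(self, value: float) -> float:
        return value / self.scale_factor

    def to_rescaled(self, value: float) -> float:
        return value * self.scale_factor


def load_image(path: str | Path) -> np.ndarray:
    """Decode a PNG/JPEG/GIF into a uint8 luminance raster.

    Color is reduced by the standard ITU-R 601 luminance weighting; any alpha
    channel is composited over white first. Only the first frame of an
    animated GIF is read.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"no such image file: {path}")
    try:
        with Image.open(path) as img:
            if img.format not in _SUPPORTED_FORMATS:
                raise InputFormatError(
                    f"unsupported image format {img.format!r} for {path} "
                    "(expected PNG, JPEG or GIF)"
                )
            img.seek(0)  # first frame only for animated GIFs
            rgba = img.convert("RGBA")
    except UnidentifiedImageError as exc:
        raise InputFormatError(f"cannot decode image file: {path}") from exc
    white = Image.new("RGBA", rgba.size, (255, 255, 255, 255))
    flat = Image.alpha_composite(white, rgba).convert("L")
    return np.asarray(flat, dtype=np.uint8)


def gray_from_binary(mask: np.ndarray) -> np.ndarray:
    """Map a foreground mask back to luminance: foreground→0, background→255."""
    return np.where(np.asarray(mask, dtype=bool), 0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> int:
    """Default global binarization threshold from the intensity histogram."""
    gray = np.asarray(gray)
    if gray.min() == gray.max():
        # Degenerate histogram: split so an all-dark image is foreground and
        # an all-light one is background.
        return 128
    return int(threshold_otsu(gray)) + 1


def binarize(gray: np.ndarray, threshold: float) -> np.ndarray:
    """Foreground mask: pixel is tree ink iff its intensity < ``threshold``."""
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ParameterError("empty raster")
    if not 0 <= threshold <= 255:
        raise ParameterError(f"threshold {threshold} outside [0, 255]")
    return gray < threshold


def estimate_horizontal_thickness(
    mask: np.ndarray, min_run: int = DEFAULT_MIN_RUN
) -> float:
    """Median vertical thickness of the horizontal lines in ``mask``.

    Samples every column interior to a maximal horizontal run of length
    ≥ ``min_run`` and measures the vertical foreground run through it, one
    sample per (column, vertical run). The median over samples is robust to
    junctions, where the vertical connector inflates the run.
    """
    mask = np.asarray(mask, dtype=bool)
    hlen = run_length_map(mask, axis=1)
    vlen = run_length_map(mask, axis=0)
    long_h = hlen >= min_run
    if not long_h.any():
        raise RecognitionError("no horizontal lines detected")
    # Sample only the top pixel of each vertical run so a k-thick bar
    # contributes one measurement per column, not k.
    above_bg = np.zeros_like(mask)
    above_bg[0, :] = mask[0, :]
    above_bg[1:, :] = mask[1:, :] & ~mask[:-1, :]
    samples = vlen[long_h & above_bg]
    if samples.size == 0:
        raise RecognitionError("no horizontal lines detected")
    return float(np.median(samples))


def _resize_nearest(mask: np.ndarray, factor: float) -> np.ndarray:
    """Center-aligned nearest-neighbor resample of a boolean raster."""
    h, w = mask.shape
    nh = max(1, round(h * factor))
    nw = max(1, round(w * factor))
    rows = np.clip(np.round((np.arange(nh) + 0.5) / factor - 0.5).astype(int), 0, h - 1)
    cols = np.clip(np.round((np.arange(nw) + 0.5) / factor - 0.5).astype(int), 0, w - 1)
    return mask[np.ix_(rows, cols)]


def _resize_bilinear_gray(gray: np.ndarray, factor: float) -> np.ndarray:
    """Center-aligned bilinear resample of a uint8 raster."""
    h, w = gray.shape
    nh = max(1, round(h * factor))
    nw = max(1, round(w * factor))
    ys = np.clip((np.arange(nh) + 0.5) / factor - 0.5, 0, h - 1)
    xs = np.clip((np.arange(nw) + 0.5) / factor - 0.5, 0, w - 1)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    fy = (ys - y0)[:, None]
    fx = (xs - x0)[None, :]
    g = gray.astype(np.float64)
    top = g[np.ix_(y0, x0)] * (1 - fx) + g[np.ix_(y0, x1)] * fx
    bot = g[np.ix_(y1, x0)] * (1 - fx) + g[np.ix_(y1, x1)] * fx
    return (top * (1 - fy) + bot * fy).round().astype(np.uint8)


def rescale_to_thickness(
    mask: np.ndarray,
    target: int = TARGET_THICKNESS,
    min_run: int = DEFAULT_MIN_RUN,
) -> tuple[np.ndarray, ScaleReport]:
    """Rescale the foreground mask so horizontal lines average ``target`` px thick.

    Downscales use nearest-neighbor sampling on the binary raster; upscales go
    through a bilinear gray resample followed by re-binarization, so no gray
    halo survives in the binary domain.
    """
    measured = estimate_horizontal_thickness(mask, min_run=min_run)
    factor = target / measured
    report = ScaleReport(measured_thickness=measured, scale_factor=factor)
    if abs(factor - 1.0) < 1e-9:
        return mask.copy(), report
    if factor < 1.0:
        out = _resize_nearest(mask, factor)
    else:
        gray = gray_from_binary(mask)
        out = _resize_bilinear_gray(gray, factor) < 128
    return out, report
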