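"""Tip-label extraction: box estimation, OCR binding, Newick sanitization.

Label boxes are estimated on the *original* image (text quality degrades
under the thickness-normalizing rescale), using the inverse scale factor to
map tip locations back. OCR itself sits behind a small engine contract with
three bindings: an external tesseract-compatible command-line program, an
injected fake for tests, and a placeholder mode that needs no external
process at all.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol

import numpy as np
from PIL import Image

from ._runs import runs_1d
from .errors import ConfigurationError
from .raster import ScaleReport


@dataclass
class LabelBox:
    """Pixel box of one tip label, in original-image coordinates."""

    tip_index: int
    x0: int
    y0: int
    x1: int
    y1: int
    empty: bool = False

    def crop(self, gray: np.ndarray) -> np.ndarray:
        return gray[self.y0 : self.y1 + 1, self.x0 : self.x1 + 1]


class OcrEngine(Protocol):
    """Contract: turn a gray label crop into text (possibly empty)."""

    name: str

    def recognize(self, region: np.ndarray) -> str: ...


class FakeOcrEngine:
    """Deterministic injected engine for tests: fixed text or a callable."""

    def __init__(self, respond: str | Callable[[np.ndarray], str] = "ABC"):
        self.name = "fake"
        self._respond = respond

    def recognize(self, region: np.ndarray) -> str:
        if callable(self._respond):
            return self._respond(region)
        return self._respond


class TesseractEngine:
    """Subprocess binding to a tesseract-compatible OCR command."""

    def __init__(self, command: str = "tesseract", lang: str | None = None):
        self.name = command
        self.lang = lang
        if shutil.which(command) is None:
            raise ConfigurationError(
                f"OCR engine {command!r} is not installed; "
                "run with OCR disabled to use placeholder labels"
            )

    def recognize(self, region: np.ndarray) -> str:
        with tempfile.TemporaryDirectory() as tmp:
            src = Path(tmp) / "crop.png"
            out = Path(tmp) / "out"
            Image.fromarray(region).save(src)
            cmd = [self.name, str(src), str(out), "--psm", "7"]
            if self.lang:
                cmd += ["-l", self.lang]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                return ""
            txt = Path(str(out) + ".txt")
            return txt.read_text() if txt.exists() else ""


#: Characters with structural meaning in Newick; labels containing any of
#: them are emitted in quoted form.
NEWICK_RESERVED = set("()[]:;,'\"")

#: Unquoted Newick labels stick to this conservative charset; anything else
#: (reserved punctuation, quotes, exotic symbols) is single-quoted.
_SAFE_LABEL = re.compile(r"[A-Za-z0-9_.+|-]+\Z")


def estimate_label_boxes(
    tips: list[tuple[float, float]],
    scale: ScaleReport,
    original_gray: np.ndarray,
    binarized_original: np.ndarray,
    gap_skip: int = 2,
) -> list[LabelBox]:
    """One label box per tip, scanned rightward from the tip end.

    The box starts at the first ink column right of the branch end, grows
    rightward until a background gap of ≥ 1.5× the estimated text height (or
    the image edge), and vertically covers the ink rows around the branch
    row, clamped to the midlines toward the adjacent tips so boxes never
    overlap in y.
    """
    h, w = binarized_original.shape
    ys_orig = [scale.to_original(y) for _, y in tips]
    xs_orig = [scale.to_original(x) for x, _ in tips]
    boxes: list[LabelBox] = []
    for i, (x_t, y_t) in enumerate(zip(xs_orig, ys_orig)):
        lo = 0.0 if i == 0 else (ys_orig[i - 1] + y_t) / 2
        hi = float(h - 1) if i == len(tips) - 1 else (ys_orig[i + 1] + y_t) / 2
        band0 = int(np.clip(np.ceil(lo), 0, h - 1))
        band1 = int(np.clip(np.floor(hi), 0, h - 1))
        band = binarized_original[band0 : band1 + 1, :]
        x_start = int(np.clip(round(x_t) + 1 + gap_skip, 0, w))
        col_has_ink = band[:, x_start:].any(axis=0)
        cols = runs_1d(col_has_ink)
        if not cols:
            boxes.append(LabelBox(i, min(x_start, w - 1), band0, min(x_start, w - 1), band1, empty=True))
            continue
        # Estimate glyph height from the first ink column group, then merge
        # groups separated by less than the adaptive stopping gap.
        g0, g1 = cols[0]
        rows = np.flatnonzero(band[:, x_start + g0 : x_start + g1].any(axis=1))
        text_h = int(rows[-1] - rows[0] + 1) if rows.size else 1
        gap_stop = max(3, round(1.5 * text_h))
        end = g1
        for s, e in cols[1:]:
            if s - end >= gap_stop:
                break
            end = e
        x0 = x_start + g0
        x1 = x_start + end - 1
        rows = np.flatnonzero(band[:, x0 : x1 + 1].any(axis=1))
        y0 = band0 + int(rows[0])
        y1 = band0 + int(rows[-1])
        boxes.append(LabelBox(i, x0, y0, x1, y1))
    return boxes


def ocr_label(
    box: LabelBox,
    original_gray: np.ndarray,
    engine: OcrEngine | None,
    pad: int = 2,
) -> str:
    """Run the engine on a padded crop; empty/absent input short-circuits."""
    if box.empty or engine is None:
        return ""
    h, w = original_gray.shape
    padded = LabelBox(
        box.tip_index,
        max(box.x0 - pad, 0),
        max(box.y0 - pad, 0),
        min(box.x1 + pad, w - 1),
        min(box.y1 + pad, h - 1),
    )
    raw = engine.recognize(padded.crop(original_gray))
    return " ".join(raw.split())


def sanitize_label(raw: str, tip_index: int) -> str:
    """Make a label safe to embed in Newick output.

    Internal whitespace becomes underscores; labels containing reserved
    punctuation are single-quoted with internal quotes doubled; an empty
    result falls back to ``tip_<k>`` (1-based).
    """
    text = "_".join(raw.split())
    if not text:
        return f"tip_{tip_index + 1}"
    if not _SAFE_LABEL.match(text):
        if len(text) == 1:
            # a lone punctuation mark carries no label information, and some
            # Newick tokenizers reject it even quoted
            return f"tip_{tip_index + 1}"
        return "'" + text.replace("'", "''") + "'"
    return text
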