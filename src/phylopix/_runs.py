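"""Vectorised run-length primitives over binary rasters.

All stages of the recognizer reason about maximal horizontal and vertical
foreground runs. These helpers compute, for every foreground pixel, the
length of the maximal run it belongs to, plus per-row run extraction used
where explicit coordinates are needed.
"""

from __future__ import annotations

import numpy as np


def run_length_map(mask: np.ndarray, axis: int = 1) -> np.ndarray:
    """Length of the maximal foreground run through each pixel, along ``axis``.

    Background pixels map to 0. ``axis=1`` measures horizontal runs,
    ``axis=0`` vertical runs.
    """
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    if axis == 0:
        return run_length_map(m.T, axis=1).T
    h, w = m.shape
    # Prepend one background column per row so runs never wrap across rows
    # after flattening.
    padded = np.concatenate([np.zeros((h, 1), dtype=bool), m], axis=1)
    flat = padded.ravel()
    shifted = np.concatenate([[False], flat[:-1]])
    starts = flat & ~shifted
    run_id = np.cumsum(starts)          # 1-based id at and after each run start
    out = np.zeros(flat.shape, dtype=np.int32)
    if run_id[-1] > 0:
        lengths = np.bincount(run_id[flat])
        out[flat] = lengths[run_id[flat]]
    return out.reshape(h, w + 1)[:, 1:]


def runs_1d(line: np.ndarray) -> list[tuple[int, int]]:
    """Maximal foreground runs of a 1-D mask as ``(start, stop)`` half-open pairs."""
    line = np.asarray(line, dtype=bool)
    if not line.any():
        return []
    padded = np.concatenate([[False], line, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def gaps_1d(line: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Background gaps of length ≤ ``max_gap`` flanked by foreground on both sides."""
    out = []
    runs = runs_1d(line)
    for (s0, e0), (s1, _) in zip(runs, runs[1:]):
        if 0 < s1 - e0 <= max_gap:
            out.append((e0, s1))
    return out
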