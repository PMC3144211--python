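"""Sliding-window smoothing of per-residue index values.

A single odd window of size ``w`` replaces each value by the mean of the
values within ``(w-1)/2`` positions on either side; windows are truncated at
the chain ends and the mean divides by the number of positions actually
included.  Because a helix is ~21 residues and the hydrocarbon core of a
bilayer corresponds to ~19, profiles are fused over a range of odd window
sizes (default 5..19) by averaging the per-window profiles, which avoids
biasing the detector toward one helix length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np


def _check_window(w: int, length: int) -> None:
    if w < 1 or w % 2 == 0:
        raise ValueError(f"window size must be a positive odd integer, got {w}")
    if w > 2 * length - 1:
        raise ValueError(f"window size {w} too large for length {length}")


def window_average(raw: Sequence[float], w: int) -> np.ndarray:
    """Boundary-truncated centered moving average with an odd window."""
    raw = np.asarray(raw, dtype=float)
    length = raw.shape[0]
    _check_window(w, length)
    if w == 1:
        return raw.copy()
    # full convolution then centered slice: correct even when w > L,
    # where numpy's mode="same" would return length w instead of L
    kernel = np.ones(w)
    half = (w - 1) // 2
    sums = np.convolve(raw, kernel, mode="full")[half : half + length]
    counts = np.convolve(np.ones(length), kernel, mode="full")[half : half + length]
    return sums / counts


def fuse_windows(
    raw: Sequence[float],
    w_min: int = 5,
    w_max: int = 19,
    weights: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Average the window profiles over all odd sizes in [w_min, w_max].

    ``weights``, if given, must have one entry per odd window size and is
    normalized to sum to 1; the default is the unweighted mean.
    """
    raw = np.asarray(raw, dtype=float)
    if w_min > w_max:
        raise ValueError(f"w_min {w_min} > w_max {w_max}")
    windows = list(range(w_min, w_max + 1, 2))
    for w in windows:
        _check_window(w, raw.shape[0])
    stack = np.stack([window_average(raw, w) for w in windows])
    if weights is None:
        return stack.mean(axis=0)
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != len(windows) or np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative, one per window, not all zero")
    return (stack * (weights / weights.sum())[:, None]).sum(axis=0)


@dataclass
class ResidueProfile:
    """Per-residue scores for one protein: raw, per-window, and fused."""

    protein_id: str
    raw: np.ndarray
    per_window: Dict[int, np.ndarray]
    fused: np.ndarray

    def __post_init__(self) -> None:
        length = self.raw.shape[0]
        if self.fused.shape[0] != length:
            raise ValueError("fused profile length mismatch")
        for w, vec in self.per_window.items():
            if vec.shape[0] != length:
                raise ValueError(f"window-{w} profile length mismatch")

    def __len__(self) -> int:
        return int(self.raw.shape[0])


def build_profile(
    protein_id: str,
    raw: Sequence[float],
    w_min: int = 5,
    w_max: int = 19,
    weights: Optional[Sequence[float]] = None,
) -> ResidueProfile:
    """Compute all window profiles and the fused profile for one protein."""
    raw = np.asarray(raw, dtype=float)
    per_window = {1: raw.copy()}
    for w in range(w_min, w_max + 1, 2):
        if w != 1:
            per_window[w] = window_average(raw, w)
    fused = fuse_windows(raw, w_min=w_min, w_max=w_max, weights=weights)
    return ResidueProfile(protein_id=protein_id, raw=raw, per_window=per_window, fused=fused)
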