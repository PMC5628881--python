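"""Marker-space windowing primitives shared by the genome scans.

Windows live in marker-index space (half-open on index); each carries
the bp span from the position of its first to its last marker.  The
same enumeration serves moving-average tracks (step < win) and
successive non-overlapping blocks (step == win).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Window:
    start_idx: int  # marker-index space, half-open [start_idx, end_idx)
    end_idx: int
    bp_start: int  # pos of first marker in the window
    bp_end: int  # pos of last marker in the window
    value: float  # statistic mean over non-missing entries (NaN if none)


@dataclass
class WindowTrack:
    chrom: str
    windows: list[Window] = field(default_factory=list)

    @property
    def values(self) -> np.ndarray:
        return np.array([w.value for w in self.windows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (self.chrom, w.start_idx, w.end_idx, w.bp_start, w.bp_end, w.value)
                for w in self.windows
            ],
            columns=[
                "chrom",
                "win_start_idx",
                "win_end_idx",
                "bp_start",
                "bp_end",
                "value",
            ],
        )


def window_bounds(n: int, win: int, step: int) -> list[tuple[int, int]]:
    """Window index bounds over ``n`` markers.

    Full windows cover [k*step, k*step + win).  A terminal partial
    window is emitted when it holds at least win/2 markers, otherwise
    the remainder merges into the last full window.  Fewer than win/2
    markers in total yield a single whole-sequence window (with a
    warning).
    """
    if win < 1 or step < 1 or step > win:
        raise ValueError("need win >= 1 and 1 <= step <= win")
    if n <= 0:
        return []
    if n < win:
        if n < win / 2:
            warnings.warn(
                f"only {n} markers for window size {win}; using one whole window",
                stacklevel=2,
            )
        return [(0, n)]
    bounds = []
    k = 0
    while k * step + win <= n:
        bounds.append((k * step, k * step + win))
        k += 1
    tail_start = k * step
    if tail_start < n and bounds[-1][1] < n:
        if n - tail_start >= win / 2:
            bounds.append((tail_start, n))
        else:
            bounds[-1] = (bounds[-1][0], n)
    return bounds


def windowed_statistic(
    values: np.ndarray, positions: np.ndarray, chrom: str, win: int, step: int
) -> WindowTrack:
    """Moving average of a per-marker statistic along one chromosome.

    ``values`` may contain NaN (skipped in each window's mean; an
    all-NaN window gets value NaN); markers must be sorted by position.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions)
    if values.shape != positions.shape:
        raise ValueError("values and positions must align")
    track = WindowTrack(chrom=str(chrom))
    for s, e in window_bounds(len(values), win, step):
        v = values[s:e]
        mean = float(np.nanmean(v)) if np.isfinite(v).any() else float("nan")
        track.windows.append(
            Window(s, e, int(positions[s]), int(positions[e - 1]), mean)
        )
    return track
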