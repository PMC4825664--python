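"""Sliding-window grids shared by the heterozygosity, IBS and coverage code.

Grid convention (pinned by tests): window starts at multiples of ``step``;
a window is ``[start, min(start + window, length))``.  If the trailing
window would be shorter than ``step`` it is merged into the previous one
(its end extends the previous window), so no window shorter than ``step``
is ever emitted and every base belongs to at least one window.
"""

from __future__ import annotations

import numpy as np


def window_grid(length: int, window: int, step: int) -> list[tuple[int, int]]:
    """Return (start, end) pairs covering ``[0, length)``."""
    if not (0 < step <= window):
        raise ValueError("require 0 < step <= window")
    if length <= 0:
        raise ValueError("length must be > 0")
    wins: list[tuple[int, int]] = []
    for start in range(0, length, step):
        wins.append((start, min(start + window, length)))
    if len(wins) > 1 and wins[-1][1] - wins[-1][0] < step:
        last = wins.pop()
        prev = wins.pop()
        wins.append((prev[0], last[1]))
    return wins


def count_in_windows(positions: np.ndarray,
                     grid: list[tuple[int, int]],
                     weights: np.ndarray | None = None) -> np.ndarray:
    """Count (or sum ``weights`` over) sorted ``positions`` per window."""
    positions = np.asarray(positions)
    starts = np.array([s for s, _ in grid])
    ends = np.array([e for _, e in grid])
    lo = np.searchsorted(positions, starts, side="left")
    hi = np.searchsorted(positions, ends, side="left")
    if weights is None:
        return (hi - lo).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(weights)])
    return csum[hi] - csum[lo]
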