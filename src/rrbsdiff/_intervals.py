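"""Sorted-array interval sets for fast point-membership queries.

Coordinates are 0-based half-open throughout the package. Overlapping input
intervals are unioned at construction, so membership tests reduce to a single
``searchsorted``. For arbitrary overlap queries between interval *sets* (DMR
annotation) the package uses :mod:`intervaltree` instead.
"""

from __future__ import annotations

import numpy as np


class IntervalSet:
    """Union of half-open intervals on one chromosome."""

    __slots__ = ("starts", "ends")

    def __init__(self, starts, ends):
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if starts.size and np.any(ends <= starts):
            raise ValueError("intervals must satisfy start < end")
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        # union overlapping / touching-by-overlap intervals
        merged_s, merged_e = [], []
        for s, e in zip(starts, ends):
            if merged_e and s < merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        self.starts = np.asarray(merged_s, dtype=np.int64)
        self.ends = np.asarray(merged_e, dtype=np.int64)

    def contains(self, positions) -> np.ndarray:
        """Boolean mask: is each point inside some interval?"""
        positions = np.asarray(positions, dtype=np.int64)
        if self.starts.size == 0:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(self.starts, positions, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(positions.shape, dtype=bool)
        hit[ok] = positions[ok] < self.ends[idx[ok]]
        return hit

    def overlaps(self, start: int, end: int) -> bool:
        """Does [start, end) overlap any interval by >= 1 bp?"""
        if self.starts.size == 0:
            return False
        i = int(np.searchsorted(self.starts, end, side="left"))
        return i > 0 and self.ends[i - 1] > start
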