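"""Small pure-numpy interval algebra used across the pipeline.

All functions take and return :class:`~pipscan.formats_io.GenomicInterval`
lists in the package-wide 0-based half-open convention.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .formats_io import GenomicInterval


def group_by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping (>= 1 bp) runs collapse to one.

    Strand is dropped ('.') — merged features are strandless.
    Output is sorted by (chrom, start).
    """
    merged: list[GenomicInterval] = []
    for chrom in sorted(group_by_chrom(intervals)):
        ivs = sorted(group_by_chrom(intervals)[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_e:  # >=1 bp overlap
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


class IntervalIndex:
    """Sorted, merged per-chromosome interval arrays for fast overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        by_chrom = group_by_chrom(merge_intervals(intervals))
        for chrom, ivs in by_chrom.items():
            self.starts[chrom] = np.array([iv.start for iv in ivs], dtype=np.int64)
            self.ends[chrom] = np.array([iv.end for iv in ivs], dtype=np.int64)

    def overlaps(self, query: GenomicInterval) -> bool:
        """True if the query shares >= 1 bp with any indexed interval."""
        starts = self.starts.get(query.chrom)
        if starts is None or len(starts) == 0:
            return False
        ends = self.ends[query.chrom]
        # merged intervals: ends are sorted too, so only the rightmost
        # interval starting before query.end can reach past query.start
        i = int(np.searchsorted(starts, query.end, side="left"))
        return i > 0 and int(ends[i - 1]) > query.start

    def overlap_bp(self, query: GenomicInterval) -> int:
        """Number of query bases covered by the indexed (merged) intervals."""
        starts = self.starts.get(query.chrom)
        if starts is None or len(starts) == 0:
            return 0
        ends = self.ends[query.chrom]
        lo = int(np.searchsorted(ends, query.start, side="right"))
        hi = int(np.searchsorted(starts, query.end, side="left"))
        total = 0
        for j in range(lo, hi):
            total += min(query.end, int(ends[j])) - max(query.start, int(starts[j]))
        return total

    def intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in sorted(self.starts):
            for s, e in zip(self.starts[chrom], self.ends[chrom]):
                out.append(GenomicInterval(chrom, int(s), int(e)))
        return out
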