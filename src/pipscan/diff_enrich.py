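"""Sliding-window chi-square differential enrichment of pulldown vs input.

The first stage of site discovery: fragments are reduced to
midpoints, counted in sliding windows, and each window's pulldown/input
counts are tested against the library-size margins with a Pearson 2x2
chi-square (no continuity correction). Significant pulldown-enriched
windows are merged into candidate regions; the stage is run at several
window sizes (default 400-1200 bp) and compiled into one candidate list.

This stage is deliberately permissive (uncorrected per-window p < 1e-4 by
default): the KS-based validation stage downstream is the guard against
false positives.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .formats_io import GenomeSequence, GenomicInterval
from .intervals import group_by_chrom

log = logging.getLogger(__name__)

DEFAULT_WINDOW_SWEEP = (400, 600, 800, 1000, 1200)


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window parameters for one differential-calling run."""

    window: int = 1000
    step: int | None = None  # default window // 4
    p_threshold: float = 1e-4
    sweep: tuple[int, ...] = DEFAULT_WINDOW_SWEEP

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        step = self.effective_step
        if not (0 < step <= self.window):
            raise ValueError("require 0 < step <= window")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")

    @property
    def effective_step(self) -> int:
        return self.step if self.step is not None else max(1, self.window // 4)

    def with_window(self, window: int) -> "WindowConfig":
        return WindowConfig(window, self.step, self.p_threshold, self.sweep)


@dataclass(frozen=True)
class CandidateRegion:
    """A differentially enriched window run awaiting motif filtering."""

    interval: GenomicInterval
    pulldown_count: int
    input_count: int
    statistic: float
    p_value: float
    window_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.pulldown_count < 0 or self.input_count < 0:
            raise ValueError("counts must be >= 0")
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value must be in [0, 1]")


def _sorted_midpoints(fragments: Sequence[GenomicInterval]) -> np.ndarray:
    mids = np.array([(f.start + f.end) // 2 for f in fragments], dtype=np.int64)
    mids.sort()
    return mids


def window_counts(
    fragments: Sequence[GenomicInterval],
    chrom: str,
    chrom_length: int,
    config: WindowConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Fragment-midpoint counts for every window fully inside the chromosome.

    Returns ``(window_starts, counts)``; a chromosome shorter than the
    window yields zero windows.
    """
    step = config.effective_step
    if chrom_length < config.window:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    n_windows = (chrom_length - config.window) // step + 1
    starts = np.arange(n_windows, dtype=np.int64) * step
    mids = _sorted_midpoints([f for f in fragments if f.chrom == chrom])
    lo = np.searchsorted(mids, starts, side="left")
    hi = np.searchsorted(mids, starts + config.window, side="left")
    return starts, hi - lo


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on [[a,b],[c,d]].

    A zero margin makes the statistic undefined; by convention that window
    is reported as (0, 1) and logged.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be >= 0")
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        log.debug("zero margin in 2x2 table (%d,%d,%d,%d); p set to 1", a, b, c, d)
        return 0.0, 1.0
    num = n * (a * d - b * c) ** 2
    den = margins[0] * margins[1] * margins[2] * margins[3]
    stat = num / den
    return float(stat), float(stats.chi2.sf(stat, df=1))


def _chi_square_vec(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray):
    a, b, c, d = (x.astype(np.float64) for x in (a, b, c, d))
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    den = r1 * r2 * c1 * c2
    ok = den > 0
    stat = np.zeros_like(n)
    np.divide(n * (a * d - b * c) ** 2, den, out=stat, where=ok)
    p = np.ones_like(n)
    p[ok] = stats.chi2.sf(stat[ok], df=1)
    return stat, p


def call_candidates(
    pulldown: Sequence[GenomicInterval],
    input_: Sequence[GenomicInterval],
    genome: GenomeSequence | Mapping[str, int],
    config: WindowConfig,
) -> list[CandidateRegion]:
    """Candidate regions at one window size.

    Each window is tested as [[window pulldown, window input],
    [rest-of-library pulldown, rest-of-library input]]; windows with
    p below threshold and pulldown enrichment above the library-size
    expectation are merged (>= 1 bp overlap) into regions, keeping the
    merged midpoint counts and the minimal p.
    """
    if not pulldown or not input_:
        raise ValueError("both samples must contain fragments")
    lengths = (
        genome.chrom_lengths
        if isinstance(genome, GenomeSequence)
        else dict(genome)
    )
    total_p, total_i = len(pulldown), len(input_)
    p_by_chrom = group_by_chrom(pulldown)
    i_by_chrom = group_by_chrom(input_)
    regions: list[CandidateRegion] = []
    for chrom, chrom_len in lengths.items():
        starts, cp = window_counts(p_by_chrom.get(chrom, []), chrom, chrom_len, config)
        _, ci = window_counts(i_by_chrom.get(chrom, []), chrom, chrom_len, config)
        if len(starts) == 0:
            continue
        stat, p = _chi_square_vec(cp, ci, total_p - cp, total_i - ci)
        enriched = cp * total_i > ci * total_p  # pulldown proportion higher
        sig = (p < config.p_threshold) & enriched
        if not sig.any():
            continue
        mids_p = _sorted_midpoints([f for f in pulldown if f.chrom == chrom])
        mids_i = _sorted_midpoints([f for f in input_ if f.chrom == chrom])
        idx = np.flatnonzero(sig)
        run_start = idx[0]
        prev = idx[0]
        runs: list[tuple[int, int]] = []
        for j in idx[1:]:
            # windows overlap when their starts differ by < window
            if starts[j] - starts[prev] < config.window:
                prev = j
            else:
                runs.append((run_start, prev))
                run_start = prev = j
        runs.append((run_start, prev))
        for first, last in runs:
            s = int(starts[first])
            e = int(starts[last]) + config.window
            best = int(first + np.argmin(p[first : last + 1]))
            n_p = int(np.searchsorted(mids_p, e) - np.searchsorted(mids_p, s))
            n_i = int(np.searchsorted(mids_i, e) - np.searchsorted(mids_i, s))
            regions.append(
                CandidateRegion(
                    GenomicInterval(chrom, s, e),
                    n_p, n_i, float(stat[best]), float(p[best]),
                    (config.window,),
                )
            )
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return regions


def compile_window_sweep(
    per_size: Sequence[Sequence[CandidateRegion]],
) -> list[CandidateRegion]:
    """Union of candidate lists from different window sizes.

    Overlapping regions (>= 1 bp) merge into one; provenance lists every
    contributing window size; the minimal p and the counts of the most
    significant contributor are retained.
    """
    flat = sorted(
        (r for lst in per_size for r in lst),
        key=lambda r: (r.interval.chrom, r.interval.start),
    )
    if not flat:
        return []
    merged: list[CandidateRegion] = []
    group = [flat[0]]
    for r in flat[1:]:
        last = group[-1]
        cur_end = max(g.interval.end for g in group)
        if r.interval.chrom == last.interval.chrom and r.interval.start < cur_end:
            group.append(r)
        else:
            merged.append(_merge_group(group))
            group = [r]
    merged.append(_merge_group(group))
    return merged


def _merge_group(group: list[CandidateRegion]) -> CandidateRegion:
    chrom = group[0].interval.chrom
    start = min(g.interval.start for g in group)
    end = max(g.interval.end for g in group)
    best = min(group, key=lambda g: g.p_value)
    sizes = tuple(sorted({w for g in group for w in g.window_sizes}))
    return CandidateRegion(
        GenomicInterval(chrom, start, end),
        best.pulldown_count, best.input_count,
        best.statistic, best.p_value, sizes,
    )


def sweep_candidates(
    pulldown: Sequence[GenomicInterval],
    input_: Sequence[GenomicInterval],
    genome: GenomeSequence | Mapping[str, int],
    config: WindowConfig | None = None,
) -> list[CandidateRegion]:
    """Run call_candidates at every sweep window size and compile."""
    config = config or WindowConfig()
    per_size = [
        call_candidates(pulldown, input_, genome, config.with_window(w))
        for w in config.sweep
    ]
    return compile_window_sweep(per_size)
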