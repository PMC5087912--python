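"""Gene/promoter annotation and chromatin-context analyses of binding sites.

Promoters are the 1000 bp immediately upstream of a transcript's TSS on its
annotated strand. Overlap anywhere in the package means >= 1 shared base.
The consensus-heterochromatin operation reproduces the >= k-of-m vote over
per-cell-line ChromHMM heterochromatin tracks (default 5 of 8).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import GenomicInterval, Transcript, read_bed
from .intervals import IntervalIndex, merge_intervals
from .site_validate import BindingSite

log = logging.getLogger(__name__)

PROMOTER_WIDTH = 1000


@dataclass(frozen=True)
class PromoterRegion:
    interval: GenomicInterval
    gene: str


class FeatureTrack:
    """A labeled, sorted, merged interval track (DHS, heterochromatin, ...)."""

    def __init__(self, intervals: Sequence[GenomicInterval], label: str = "custom"):
        self.label = label
        self._index = IntervalIndex(intervals)

    @classmethod
    def from_bed(cls, path, label: str = "custom") -> "FeatureTrack":
        return cls(read_bed(path), label=label)

    @property
    def intervals(self) -> list[GenomicInterval]:
        return self._index.intervals()

    def overlaps(self, interval: GenomicInterval) -> bool:
        return self._index.overlaps(interval)

    def coverage_bp(self, interval: GenomicInterval) -> int:
        return self._index.overlap_bp(interval)

    def is_empty_on(self, chrom: str) -> bool:
        starts = self._index.starts.get(chrom)
        return starts is None or len(starts) == 0

    def total_bp(self, chrom: str | None = None) -> int:
        total = 0
        for c, starts in self._index.starts.items():
            if chrom is not None and c != chrom:
                continue
            total += int((self._index.ends[c] - starts).sum())
        return total


def promoter_of(
    tx: Transcript, chrom_length: int | None = None
) -> PromoterRegion:
    """The strand-aware 1000 bp upstream of the TSS, clamped to the chrom."""
    if tx.strand == "+":
        start = max(0, tx.tx_start - PROMOTER_WIDTH)
        end = tx.tx_start
    else:
        start = tx.tx_end
        end = tx.tx_end + PROMOTER_WIDTH
        if chrom_length is not None:
            end = min(end, chrom_length)
    return PromoterRegion(GenomicInterval(tx.chrom, start, end, tx.strand), tx.gene)


def annotate_sites(
    sites: Sequence[BindingSite],
    transcripts: Sequence[Transcript],
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[list[BindingSite], dict[str, int]]:
    """Label each site with every overlapping transcript and promoter.

    Sites overlapping neither are intergenic. Returns the annotated sites
    and summary counts (in_transcript, in_promoter, intergenic).
    """
    promoters = [
        promoter_of(tx, chrom_lengths.get(tx.chrom) if chrom_lengths else None)
        for tx in transcripts
    ]
    annotated: list[BindingSite] = []
    n_tx = n_prom = n_inter = 0
    for site in sites:
        genes = tuple(
            sorted({tx.gene for tx in transcripts if site.interval.overlaps(tx.interval)})
        )
        proms = tuple(
            sorted({p.gene for p in promoters if site.interval.overlaps(p.interval)})
        )
        if genes:
            n_tx += 1
        if proms:
            n_prom += 1
        if not genes and not proms:
            n_inter += 1
        annotated.append(replace(site, genes=genes, promoters=proms))
    return annotated, {
        "in_transcript": n_tx,
        "in_promoter": n_prom,
        "intergenic": n_inter,
    }


def closest_feature_distance(
    site: GenomicInterval, track: FeatureTrack
) -> tuple[int, GenomicInterval] | None:
    """Distance in bp from a site to the nearest feature on its chromosome.

    0 when overlapping; otherwise the gap between nearest edges. Ties are
    broken toward the smaller coordinate. None when the chromosome carries
    no features (caller flags the site as missing).
    """
    if track.is_empty_on(site.chrom):
        return None
    starts = track._index.starts[site.chrom]
    ends = track._index.ends[site.chrom]
    best: tuple[int, int] | None = None  # (distance, start) for tie-break
    i = int(np.searchsorted(starts, site.end, side="left"))
    for j in (i - 1, i):
        if 0 <= j < len(starts):
            s, e = int(starts[j]), int(ends[j])
            if s < site.end and site.start < e:
                dist = 0
            elif e <= site.start:
                dist = site.start - e
            else:
                dist = s - site.end
            cand = (dist, s)
            if best is None or cand[0] < best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best = cand
    assert best is not None
    dist, s = best
    j = int(np.searchsorted(starts, s))
    return dist, GenomicInterval(site.chrom, int(starts[j]), int(ends[j]))


def consensus_heterochromatin(
    tracks: Sequence[FeatureTrack], k: int = 5
) -> FeatureTrack:
    """Maximal intervals supported by >= k of the supplied tracks.

    Implemented as an event sweep over interval endpoints (no per-base
    materialization), so it scales to chromosome-sized tracks.
    """
    if len(tracks) < k:
        raise ValueError(f"need >= {k} tracks, got {len(tracks)}")
    chroms = sorted({c for t in tracks for c in t._index.starts})
    consensus: list[GenomicInterval] = []
    for chrom in chroms:
        events: list[tuple[int, int]] = []
        for t in tracks:
            starts = t._index.starts.get(chrom)
            if starts is None:
                continue
            for s, e in zip(starts, t._index.ends[chrom]):
                events.append((int(s), +1))
                events.append((int(e), -1))
        events.sort()
        depth = 0
        run_start: int | None = None
        idx = 0
        while idx < len(events):
            pos = events[idx][0]
            while idx < len(events) and events[idx][0] == pos:
                depth += events[idx][1]
                idx += 1
            if depth >= k and run_start is None:
                run_start = pos
            elif depth < k and run_start is not None:
                consensus.append(GenomicInterval(chrom, run_start, pos))
                run_start = None
    return FeatureTrack(consensus, label="heterochromatin")


def dhs_position_profile(
    sites: Sequence[BindingSite],
    dhs: FeatureTrack,
    chrom_lengths: Mapping[str, int],
    bin_size: int = 10_000,
) -> tuple[pd.DataFrame, list[bool]]:
    """Per-bin DHS coverage percentage and per-site inside/outside flags.

    The final, possibly incomplete bin of each chromosome is kept and
    normalized by its true width; a site is inside when it overlaps DHS by
    >= 1 bp.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            covered = dhs.coverage_bp(GenomicInterval(chrom, start, end))
            rows.append(
                {"chrom": chrom, "bin_start": start,
                 "dhs_pct": 100.0 * covered / (end - start)}
            )
    flags = [dhs.overlaps(s.interval) for s in sites]
    return pd.DataFrame(rows), flags


def chromatin_odds(
    sites: Sequence[BindingSite],
    track: FeatureTrack,
    mode: str = "within_over_outside",
) -> float:
    """Ratio of site counts on the two sides of a chromatin track.

    within_over_outside: sites overlapping the track / sites outside
    (the DHS convention); outside_over_within is the heterochromatin
    convention. Zero denominator is an error.
    """
    if mode not in ("within_over_outside", "outside_over_within"):
        raise ValueError(f"unknown mode {mode!r}")
    inside = sum(1 for s in sites if track.overlaps(s.interval))
    outside = len(sites) - inside
    num, den = (
        (inside, outside) if mode == "within_over_outside" else (outside, inside)
    )
    if den == 0:
        raise ValueError("zero denominator in chromatin odds")
    return num / den
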