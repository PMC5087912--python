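"""9-mer composition comparison between binding-site neighborhoods and a
reference transcript.

Binding sites that overlap a feature track of interest (e.g. lncRNA
annotation) are extracted with 1000-bp flanks — 2009 bp for an interior
9-bp site — and their k-mer spectrum is compared against the spectrum of a
reference region. Windows containing N (masked repeats) are skipped;
strands are counted as given (no canonicalization).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotate_features import FeatureTrack
from .formats_io import GenomeSequence, GenomicInterval
from .site_validate import BindingSite

DEFAULT_FLANK = 1000


@dataclass(frozen=True)
class FlankedRegion:
    interval: GenomicInterval
    sequence: str
    clamped: bool


@dataclass(frozen=True)
class KmerProfile:
    k: int
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct(self) -> frozenset[str]:
        return frozenset(self.counts)


def extract_flanked_regions(
    sites: Sequence[BindingSite | GenomicInterval],
    track: FeatureTrack,
    genome: GenomeSequence,
    flank: int = DEFAULT_FLANK,
) -> list[FlankedRegion]:
    """Sites overlapping the track (>= 1 bp), widened by ``flank`` on each
    side; records truncated at a chromosome end are flagged clamped."""
    lengths = genome.chrom_lengths
    out: list[FlankedRegion] = []
    for site in sites:
        iv = site.interval if isinstance(site, BindingSite) else site
        if not track.overlaps(iv):
            continue
        region = iv.expand(flank, lengths[iv.chrom])
        clamped = region.width != iv.width + 2 * flank
        out.append(FlankedRegion(region, genome.fetch(region), clamped))
    return out


def count_kmers(sequences: Iterable[str], k: int = 9) -> KmerProfile:
    """Sliding-window k-mer counts; any window containing N is skipped."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter[str] = Counter()
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                counts[kmer] += 1
    return KmerProfile(k, dict(counts))


def shared_kmer_similarity(
    profile_a: KmerProfile, profile_b: KmerProfile
) -> tuple[int, float, float]:
    """(shared distinct k-mers, Jaccard over distinct sets, fraction of A's
    distinct k-mers present in B)."""
    if profile_a.k != profile_b.k:
        raise ValueError("profiles must use the same k")
    a, b = profile_a.distinct, profile_b.distinct
    shared = len(a & b)
    union = len(a | b)
    jaccard = shared / union if union else 0.0
    frac_a = shared / len(a) if a else 0.0
    return shared, jaccard, frac_a
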