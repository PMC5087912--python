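"""Sample-specific sequence reconstruction over candidate regions.

Motif matching should run on the cell line's actual sequence, not the
reference: SNVs and indels called over a candidate region are substituted
into the reference slice, and match coordinates are mapped back to
reference coordinates through a monotone offset map. Indels shift the map;
a match whose reference footprint differs from the motif length is flagged
as indel-spanning.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats_io import GenomeSequence, GenomicInterval

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Variant:
    """A VCF-style variant: 0-based reference offset, anchored alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("variant position must be >= 0")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")

    @property
    def end(self) -> int:
        return self.pos + len(self.ref)


@dataclass(frozen=True)
class ReconstructedRegion:
    """A variant-substituted region with its reference coordinate map.

    ``offset_map[i]`` is the reference offset of reconstructed base ``i``:
    substituted bases map to their reference positions, inserted bases map
    to the preceding reference base, and deleted reference bases are simply
    absent from the map's range.
    """

    region: GenomicInterval
    sequence: str
    offset_map: np.ndarray  # int64, len == len(sequence), non-decreasing

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.offset_map):
            raise ValueError("offset map length must equal sequence length")
        if len(self.offset_map) and (
            np.any(np.diff(self.offset_map) < 0)
            or self.offset_map[0] < self.region.start
            or self.offset_map[-1] >= self.region.end
        ):
            raise ValueError("offset map must be monotone and within the region")


def apply_variants(
    genome: GenomeSequence,
    region: GenomicInterval,
    variants: Sequence[Variant],
) -> ReconstructedRegion:
    """Substitute sorted, non-overlapping variants into a reference region.

    Only variants fully inside the region are applied; ref alleles are
    verified against the reference and a mismatch is an error. One alternate
    allele per locus (a single consensus haplotype).
    """
    ref_seq = genome.fetch(region)
    inside = sorted(
        (v for v in variants
         if v.chrom == region.chrom and v.pos >= region.start and v.end <= region.end),
        key=lambda v: v.pos,
    )
    prev_end = region.start
    for v in inside:
        if v.pos < prev_end:
            raise ValueError(f"overlapping variants at {v.chrom}:{v.pos}")
        observed = ref_seq[v.pos - region.start : v.end - region.start]
        if observed != v.ref.upper():
            raise ValueError(
                f"ref allele mismatch at {v.chrom}:{v.pos}: "
                f"expected {v.ref!r}, reference has {observed!r}"
            )
        prev_end = v.end
    pieces: list[str] = []
    offsets: list[int] = []
    cursor = region.start
    for v in inside:
        between = ref_seq[cursor - region.start : v.pos - region.start]
        pieces.append(between)
        offsets.extend(range(cursor, v.pos))
        alt = v.alt.upper()
        pieces.append(alt)
        # alt base j maps to pos + min(j, len(ref)-1): substituted bases to
        # their own reference base, inserted bases to the preceding one
        offsets.extend(v.pos + min(j, len(v.ref) - 1) for j in range(len(alt)))
        cursor = v.end
    pieces.append(ref_seq[cursor - region.start :])
    offsets.extend(range(cursor, region.end))
    return ReconstructedRegion(
        region, "".join(pieces), np.asarray(offsets, dtype=np.int64)
    )


def backmap_match(
    offset: int, k: int, recon: ReconstructedRegion
) -> tuple[GenomicInterval, bool]:
    """Reference interval of a k-bp match at ``offset`` in reconstructed space.

    Returns ``(interval, indel_spanning)``; the flag is set when the
    reference footprint differs from k (the match crosses an indel).
    """
    if offset < 0 or offset + k > len(recon.sequence):
        raise ValueError(
            f"match [{offset},{offset + k}) outside reconstructed "
            f"sequence of length {len(recon.sequence)}"
        )
    ref_start = int(recon.offset_map[offset])
    ref_end = int(recon.offset_map[offset + k - 1]) + 1
    interval = GenomicInterval(recon.region.chrom, ref_start, ref_end)
    return interval, interval.width != k


def read_vcf(path: str | Path) -> list[Variant]:
    """Minimal VCF reader: CHROM, POS (1-based, converted here), REF, ALT.

    FILTER/INFO are ignored; multi-allelic ALT records are rejected with a
    warning (one consensus haplotype per locus).
    """
    variants: list[Variant] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ValueError(f"{path}:{lineno}: expected >= 5 VCF columns")
            chrom, pos, _id, ref, alt = cols[:5]
            if "," in alt:
                log.warning("%s:%d: multi-allelic ALT rejected", path, lineno)
                continue
            variants.append(Variant(chrom, int(pos) - 1, ref.upper(), alt.upper()))
    return variants


def write_vcf(variants: Sequence[Variant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\n")
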