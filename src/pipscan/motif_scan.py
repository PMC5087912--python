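"""Degenerate (IUPAC) motif matching and the scrambled-motif audit.

The flagship motif is the 9-bp polyamide recognition sequence
5'-TGWWGGCGW-3' (W = A or T). Matching is exact-degenerate on both strands;
N in the subject sequence never matches any motif letter.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formats_io import GenomeSequence, GenomicInterval
from .intervals import IntervalIndex

KR12_MOTIF = "TGWWGGCGW"

# IUPAC ambiguity codes -> the set of concrete bases they match.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


@dataclass(frozen=True)
class Motif:
    """An IUPAC degenerate motif; W<->W under reverse complement."""

    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("motif must have length >= 1")
        bad = set(self.sequence.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC motif letter {sorted(bad)[0]}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence

    def reverse_complement(self) -> "Motif":
        return Motif("".join(_COMPLEMENT[b] for b in reversed(self.sequence)))

    def regex(self) -> re.Pattern:
        """Overlap-tolerant lookahead pattern; N in the subject never matches
        because character classes contain concrete bases only."""
        body = "".join(
            b if len(IUPAC[b]) == 1 else f"[{IUPAC[b]}]" for b in self.sequence
        )
        return re.compile(f"(?={body})")

    def concrete_expansions(self) -> list[str]:
        """All concrete k-mers the motif matches (oracle-sized motifs only)."""
        seqs = [""]
        for b in self.sequence:
            seqs = [s + c for s in seqs for c in IUPAC[b]]
        return seqs


@dataclass(frozen=True)
class MotifMatch:
    interval: GenomicInterval
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be forward or reverse")


def match_motif(
    sequence: str,
    motif: Motif | str,
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifMatch]:
    """All offsets where the motif or its reverse complement matches.

    Overlapping matches are all reported; an offset matching in both
    orientations yields two records. Coordinates are reported in the
    subject's frame shifted by ``offset`` (so candidate-region scans can
    report chromosome coordinates directly).
    """
    motif = Motif(str(motif))
    sequence = sequence.upper()
    k = len(motif)
    out: list[MotifMatch] = []
    for orientation, pattern in (
        ("forward", motif.regex()),
        ("reverse", motif.reverse_complement().regex()),
    ):
        for m in pattern.finditer(sequence):
            s = m.start() + offset
            strand = "+" if orientation == "forward" else "-"
            out.append(
                MotifMatch(GenomicInterval(chrom, s, s + k, strand), orientation)
            )
    out.sort(key=lambda m: (m.interval.start, m.orientation))
    return out


def catalog_hypothetical_sites(
    genome: GenomeSequence, motif: Motif | str
) -> list[MotifMatch]:
    """Genome-wide motif matches on both strands, sorted by (chrom, start)."""
    matches: list[MotifMatch] = []
    for chrom, seq in genome.items():
        matches.extend(match_motif(seq, motif, chrom=chrom))
    matches.sort(key=lambda m: (m.interval.chrom, m.interval.start, m.orientation))
    return matches


def deduplicate_positions(matches: Iterable[MotifMatch]) -> list[GenomicInterval]:
    """Collapse strand-events to unique positions (chrom, start, end)."""
    seen: dict[tuple[str, int, int], GenomicInterval] = {}
    for m in matches:
        key = (m.interval.chrom, m.interval.start, m.interval.end)
        if key not in seen:
            seen[key] = GenomicInterval(*key)
    return [seen[k] for k in sorted(seen)]


def site_counts(matches: Sequence[MotifMatch]) -> dict[str, int]:
    """Both tallies of genome-wide sites: per-strand events and unique
    positions (a position matching in both orientations counts once)."""
    return {
        "strand_events": len(matches),
        "unique_positions": len(deduplicate_positions(matches)),
    }


def scramble_motifs(motif: Motif | str, n: int, seed: int) -> list[Motif]:
    """n random scrambles of the motif with the 5' base fixed.

    The first letter is kept (it anchors the alkylating moiety); the
    remaining letters are uniformly permuted, independently per draw
    (duplicates across draws are possible).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    motif = Motif(str(motif))
    if len(motif) < 2:
        raise ValueError("motif must have length >= 2 to scramble")
    rng = np.random.default_rng(seed)
    head, tail = motif.sequence[0], list(motif.sequence[1:])
    out = []
    for _ in range(n):
        perm = rng.permutation(len(tail))
        out.append(Motif(head + "".join(tail[i] for i in perm)))
    return out


def motif_site_ratios(
    genome: GenomeSequence,
    motifs: Sequence[Motif | str],
    reference_motif: Motif | str,
    cds: Sequence[GenomicInterval],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-motif site counts relative to a reference motif (genome-wide and
    CDS-overlapping), plus the reference's mid-rank percentile within the
    scrambled population on both metrics.

    Counts are unique positions; CDS overlap is >= 1 bp.
    """
    cds_index = IntervalIndex(cds) if cds else None

    def counts(m: Motif | str) -> tuple[int, int]:
        positions = deduplicate_positions(catalog_hypothetical_sites(genome, m))
        g = len(positions)
        c = sum(1 for p in positions if cds_index is not None and cds_index.overlaps(p))
        return g, c

    ref_g, ref_c = counts(reference_motif)
    if ref_g == 0:
        raise ValueError("reference motif absent from genome")
    rows = []
    for m in motifs:
        g, c = counts(m)
        rows.append(
            {
                "motif": str(Motif(str(m))),
                "genome_count": g,
                "cds_count": c,
                "genome_ratio": g / ref_g,
                "cds_ratio": (c / ref_c) if ref_c > 0 else float("nan"),
            }
        )
    df = pd.DataFrame(rows)

    def midrank_percentile(values: np.ndarray, ref: float) -> float:
        less = np.sum(values < ref)
        equal = np.sum(values == ref)
        return 100.0 * (less + 0.5 * equal) / len(values)

    percentiles = {
        "genome": midrank_percentile(df["genome_count"].to_numpy(), ref_g),
        "cds": midrank_percentile(df["cds_count"].to_numpy(), ref_c),
    }
    return df, percentiles
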