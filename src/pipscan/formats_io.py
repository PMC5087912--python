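"""Genomic file formats and the coordinate types every stage exchanges.

One convention everywhere: coordinates are 0-based, half-open ``[start, end)``
(BED-native). External dialects that are 1-based (VCF POS) are converted at
the I/O boundary and nowhere else.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

log = logging.getLogger(__name__)

STRANDS = frozenset({"+", "-", "."})
DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def expand(self, flank: int, chrom_length: int | None = None) -> "GenomicInterval":
        """Widen by ``flank`` bp on each side, clamped to the chromosome."""
        start = max(0, self.start - flank)
        end = self.end + flank
        if chrom_length is not None:
            end = min(end, chrom_length)
        return GenomicInterval(self.chrom, start, end, self.strand)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


class GenomeSequence:
    """Uppercase DNA over {A,C,G,T,N}, one string per chromosome."""

    def __init__(self, chroms: Mapping[str, str]):
        cleaned: dict[str, str] = {}
        for name, seq in chroms.items():
            if not name:
                raise ValueError("chromosome name must be non-empty")
            seq = seq.upper()
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"illegal character {sorted(bad)[0]} in chromosome {name}"
                )
            cleaned[name] = seq
        self._chroms = cleaned

    @property
    def chrom_names(self) -> list[str]:
        return list(self._chroms)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._chroms.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def __getitem__(self, chrom: str) -> str:
        return self._chroms[chrom]

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of ``interval``; always exactly ``end - start`` letters."""
        seq = self._chroms[interval.chrom]
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval} exceeds chromosome length {len(seq)}"
            )
        return seq[interval.start : interval.end]

    def items(self):
        return self._chroms.items()


@dataclass(frozen=True)
class Transcript:
    """A refFlat transcript record (UCSC 0-based half-open convention)."""

    gene: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene}: txStart must be < txEnd")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.gene}: CDS must lie within the transcript")
        prev_end = self.tx_start
        for s, e in self.exons:
            if s >= e or s < self.tx_start or e > self.tx_end:
                raise ValueError(f"{self.gene}: malformed exon [{s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.gene}: exons overlap or are unsorted")
            prev_end = e

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end, self.strand)


class CoverageTrack:
    """Per-base sequencing depth, one non-negative vector per chromosome."""

    def __init__(self, data: Mapping[str, np.ndarray], label: str = "pulldown"):
        self.label = label
        self._data = {c: np.asarray(v, dtype=float) for c, v in data.items()}
        for chrom, vec in self._data.items():
            if np.any(vec < 0):
                raise ValueError(f"negative depth on {chrom}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._data

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self._data[chrom]

    def fetch(self, interval: GenomicInterval) -> np.ndarray:
        return self._data[interval.chrom][interval.start : interval.end]

    def items(self):
        return self._data.items()

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(v) for c, v in self._data.items()}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a multi-record FASTA into memory, uppercased and validated."""
    path = Path(path)
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record {rec.id}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(records)


def write_fasta(genome: GenomeSequence | Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    items = genome.items() if hasattr(genome, "items") else genome
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Parse BED3+/BED6; column 6, when present, is the strand.

    Records with start >= end are rejected with a warning (not fatal);
    non-integer coordinates are a parse error.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                log.warning("%s:%d: start >= end, record rejected", path, lineno)
                continue
            strand = cols[5] if len(cols) >= 6 and cols[5] in STRANDS else "."
            intervals.append(GenomicInterval(cols[0], start, end, strand))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6 (name '.', score 0); coordinates round-trip bit-exactly."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_refflat(path: str | Path) -> list[Transcript]:
    """Parse UCSC refFlat (11 columns, comma-separated exon lists).

    Records whose exonCount disagrees with the exon lists are rejected with
    a warning, mirroring how malformed annotation rows are usually handled.
    """
    transcripts: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 11:
                raise ValueError(f"{path}:{lineno}: expected 11 refFlat columns")
            gene, _name, chrom, strand = cols[0], cols[1], cols[2], cols[3]
            tx_start, tx_end = int(cols[4]), int(cols[5])
            cds_start, cds_end = int(cols[6]), int(cols[7])
            exon_count = int(cols[8])
            starts = [int(x) for x in cols[9].rstrip(",").split(",") if x]
            ends = [int(x) for x in cols[10].rstrip(",").split(",") if x]
            if len(starts) != exon_count or len(ends) != exon_count:
                log.warning(
                    "%s:%d: exonCount %d disagrees with exon lists, rejected",
                    path, lineno, exon_count,
                )
                continue
            transcripts.append(
                Transcript(gene, chrom, strand, tx_start, tx_end,
                           cds_start, cds_end, tuple(zip(starts, ends)))
            )
    return transcripts


def write_refflat(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            starts = ",".join(str(s) for s, _ in tx.exons) + ","
            ends = ",".join(str(e) for _, e in tx.exons) + ","
            fh.write(
                f"{tx.gene}\t{tx.gene}\t{tx.chrom}\t{tx.strand}\t{tx.tx_start}"
                f"\t{tx.tx_end}\t{tx.cds_start}\t{tx.cds_end}\t{len(tx.exons)}"
                f"\t{starts}\t{ends}\n"
            )


def coverage_from_fragments(
    fragments: Sequence[GenomicInterval],
    genome: GenomeSequence | Mapping[str, int],
    label: str = "pulldown",
) -> CoverageTrack:
    """Per-base depth: depth(b) = number of fragments covering base b.

    Fragments extending past a chromosome end are clipped (with a warning);
    fragments on unknown chromosomes are skipped.
    """
    lengths = (
        genome.chrom_lengths if isinstance(genome, GenomeSequence) else dict(genome)
    )
    delta = {c: np.zeros(n + 1) for c, n in lengths.items()}
    n_clipped = n_skipped = 0
    for frag in fragments:
        if frag.chrom not in delta:
            n_skipped += 1
            continue
        n = lengths[frag.chrom]
        start, end = frag.start, min(frag.end, n)
        if start >= n:
            n_skipped += 1
            continue
        if end != frag.end:
            n_clipped += 1
        delta[frag.chrom][start] += 1
        delta[frag.chrom][end] -= 1
    if n_skipped:
        log.warning("%d fragments on unknown chromosomes or out of bounds, skipped",
                    n_skipped)
    if n_clipped:
        log.warning("%d fragments clipped at chromosome ends", n_clipped)
    data = {c: np.cumsum(d[:-1]) for c, d in delta.items()}
    return CoverageTrack(data, label=label)


def read_bedgraph(
    path: str | Path,
    chrom_lengths: Mapping[str, int],
    label: str = "pulldown",
) -> CoverageTrack:
    """bedGraph -> CoverageTrack; overlapping records are summed (coverage
    is additive). Records on unknown chromosomes are skipped with a warning.
    """
    data = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            if chrom not in data:
                n_skipped += 1
                continue
            s, e = int(start), min(int(end), len(data[chrom]))
            if s >= e:
                raise ValueError(f"{path}:{lineno}: empty bedGraph interval")
            data[chrom][s:e] += float(value)
    if n_skipped:
        log.warning("%d bedGraph records on unknown chromosomes skipped", n_skipped)
    return CoverageTrack(data, label=label)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Run-length-encoded bedGraph; zero-depth runs are omitted."""
    with open(path, "w") as fh:
        for chrom, vec in track.items():
            if len(vec) == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0:
                    text = f"{v:.6g}"
                    fh.write(f"{chrom}\t{s}\t{e}\t{text}\n")
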