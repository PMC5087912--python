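"""Self-contained synthetic fixtures with ground truth for every stage.

The generator emulates the study's inputs: a random genome with implanted
motif instances (enriched "true" sites and non-enriched decoys), pulldown
and input fragment sets from a sonication-style model, a tiled transcript
annotation, and a differential-expression table in which bound genes carry
a negative log2FC shift. Defaults mirror the study conditions used by the
validation experiments: a 2-Mb genome, 20 true sites, 200 decoys,
background 0.05 fragments/bp, 8-fold enrichment, and an expression table
of 2000 genes with 200 bound genes shifted by -0.5 at noise SD 0.3.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .formats_io import GenomeSequence, GenomicInterval, Transcript
from .motif_scan import IUPAC, KR12_MOTIF, Motif, catalog_hypothetical_sites, \
    deduplicate_positions

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationParams:
    """Study-condition knobs for the synthetic generator."""

    genome_length: int = 2_000_000
    n_chromosomes: int = 1
    gc_fraction: float = 0.41  # human-like background composition
    motif: str = KR12_MOTIF
    n_true_sites: int = 20
    n_decoy_sites: int = 200
    min_separation: int = 3000  # keeps decision windows of implants disjoint
    edge_margin: int = 2000
    background_rate: float = 0.05  # fragments per base
    enrichment: float = 8.0
    fragment_mean: float = 200.0  # Covaris-style sonication model
    fragment_sd: float = 50.0
    fragment_min: int = 50
    n_genes: int = 2000
    n_bound_genes: int = 200
    expression_shift: float = -0.5  # delta: bound-gene log2FC shift
    expression_sd: float = 0.3
    expression_replicates: int = 3
    strict_background: bool = True  # reject accidental motif matches
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment < 1.0:
            raise ValueError("enrichment factor must be >= 1")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must be in [0, 1]")
        need = (self.n_true_sites + self.n_decoy_sites) * len(self.motif) * 10
        if self.genome_length < need:
            raise ValueError(
                f"genome too short: need >= {need} bp for the requested sites"
            )


@dataclass
class TruthSet:
    """Ground truth of one simulated study."""

    true_sites: list[GenomicInterval]
    decoy_sites: list[GenomicInterval]
    bound_genes: list[str] = field(default_factory=list)
    true_log2fc: dict[str, float] = field(default_factory=dict)


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def _concrete_instance(rng: np.random.Generator, motif: Motif) -> str:
    return "".join(
        b if len(IUPAC[b]) == 1 else IUPAC[b][rng.integers(len(IUPAC[b]))]
        for b in motif.sequence
    )


_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp(seq: str) -> str:
    return seq.encode()[::-1].translate(_COMP).decode()


def simulate_genome(
    params: SimulationParams,
) -> tuple[GenomeSequence, TruthSet]:
    """Random background genome with implanted motif instances.

    True sites and decoys are concrete W-resolutions of the motif implanted
    at non-overlapping, well-separated positions with random orientation.
    In strict mode, accidental background matches are rewritten (without
    touching implants) until the genome-wide catalog contains exactly the
    implanted positions.
    """
    rng = np.random.default_rng(params.seed)
    motif = Motif(params.motif)
    k = len(motif)
    n_sites = params.n_true_sites + params.n_decoy_sites
    per_chrom = params.genome_length // params.n_chromosomes
    chrom_names = [f"chr{i + 1}" for i in range(params.n_chromosomes)]
    arrays = {c: _random_background(rng, per_chrom, params.gc_fraction)
              for c in chrom_names}

    # slot-based placement guarantees the separation invariant
    slots: list[tuple[str, int]] = []
    for c in chrom_names:
        lo, hi = params.edge_margin, per_chrom - params.edge_margin - k
        slots.extend((c, int(p)) for p in range(lo, hi, params.min_separation))
    if len(slots) < n_sites:
        raise ValueError(
            f"cannot place {n_sites} sites with separation "
            f"{params.min_separation} in this genome"
        )
    chosen = rng.choice(len(slots), size=n_sites, replace=False)
    implants: list[GenomicInterval] = []
    for idx in chosen:
        chrom, pos = slots[int(idx)]
        jitter = int(rng.integers(0, max(1, params.min_separation - k - 1000)))
        pos = min(pos + jitter, per_chrom - params.edge_margin - k)
        inst = _concrete_instance(rng, motif)
        if rng.random() < 0.5:
            inst = _revcomp(inst)
            strand = "-"
        else:
            strand = "+"
        arrays[chrom][pos : pos + k] = np.frombuffer(inst.encode(), dtype="S1")
        implants.append(GenomicInterval(chrom, pos, pos + k, strand))
    implants.sort(key=lambda iv: (iv.chrom, iv.start))

    genome = GenomeSequence(
        {c: a.tobytes().decode() for c, a in arrays.items()}
    )
    if params.strict_background:
        genome = _scrub_accidental_matches(genome, arrays, motif, implants, rng)

    order = rng.permutation(n_sites)
    true_idx = set(int(i) for i in order[: params.n_true_sites])
    truth = TruthSet(
        true_sites=[iv for i, iv in enumerate(implants) if i in true_idx],
        decoy_sites=[iv for i, iv in enumerate(implants) if i not in true_idx],
    )
    return genome, truth


def _scrub_accidental_matches(
    genome: GenomeSequence,
    arrays: dict[str, np.ndarray],
    motif: Motif,
    implants: Sequence[GenomicInterval],
    rng: np.random.Generator,
    max_rounds: int = 100,
) -> GenomeSequence:
    implant_keys = {(iv.chrom, iv.start, iv.end) for iv in implants}
    implant_mask = {
        c: np.zeros(len(a), dtype=bool) for c, a in arrays.items()
    }
    for iv in implants:
        implant_mask[iv.chrom][iv.start : iv.end] = True
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for round_ in range(max_rounds):
        accidental = [
            p for p in deduplicate_positions(catalog_hypothetical_sites(genome, motif))
            if (p.chrom, p.start, p.end) not in implant_keys
        ]
        if not accidental:
            return genome
        for p in accidental:
            window = np.arange(p.start, p.end)
            free = window[~implant_mask[p.chrom][p.start : p.end]]
            if len(free) == 0:  # fully inside an implant: overlapping hit, keep
                continue
            arrays[p.chrom][free] = bases[rng.integers(0, 4, size=len(free))]
        genome = GenomeSequence({c: a.tobytes().decode() for c, a in arrays.items()})
    raise RuntimeError("could not scrub accidental motif matches")


def simulate_fragments(
    genome: GenomeSequence,
    truth: TruthSet,
    params: SimulationParams,
    seed: int | None = None,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Pulldown and input fragment sets.

    Input: Poisson-uniform fragment starts at the background rate, lengths
    truncated-Normal(mean, sd) with a floor. Pulldown: an independent draw
    of the same background process plus, at each true site, extra fragments
    centered on the site with Normal jitter (SD = mean length / 4) at rate
    (enrichment - 1) x background depth. Decoys receive no extra mass.
    """
    rng = np.random.default_rng(params.seed + 101 if seed is None else seed)
    lengths = genome.chrom_lengths

    def frag_lengths(n: int) -> np.ndarray:
        ln = rng.normal(params.fragment_mean, params.fragment_sd, size=n)
        return np.maximum(np.round(ln), params.fragment_min).astype(np.int64)

    def background() -> list[GenomicInterval]:
        frags: list[GenomicInterval] = []
        for chrom, clen in lengths.items():
            n = rng.poisson(params.background_rate * clen)
            starts = rng.integers(0, clen, size=n)
            lens = frag_lengths(n)
            ends = np.minimum(starts + lens, clen)
            keep = ends > starts
            frags.extend(
                GenomicInterval(chrom, int(s), int(e))
                for s, e in zip(starts[keep], ends[keep])
            )
        return frags

    input_frags = background()
    pulldown_frags = background()
    extra_rate = (params.enrichment - 1.0) * params.background_rate
    mean_extra = extra_rate * params.fragment_mean
    for site in truth.true_sites:
        clen = lengths[site.chrom]
        n_extra = rng.poisson(mean_extra)
        centers = rng.normal(
            (site.start + site.end) / 2.0, params.fragment_mean / 4.0, size=n_extra
        )
        lens = frag_lengths(n_extra)
        starts = np.maximum(np.round(centers - lens / 2.0), 0).astype(np.int64)
        ends = np.minimum(starts + lens, clen)
        keep = ends > starts
        pulldown_frags.extend(
            GenomicInterval(site.chrom, int(s), int(e))
            for s, e in zip(starts[keep], ends[keep])
        )
    return pulldown_frags, input_frags


def simulate_transcripts(
    genome: GenomeSequence,
    n_genes: int,
    tx_length: int = 4000,
    seed: int = 0,
) -> list[Transcript]:
    """Non-overlapping two-exon transcripts tiled along the genome with
    alternating strands; gene symbols GENE0001, GENE0002, ..."""
    rng = np.random.default_rng(seed)
    lengths = genome.chrom_lengths
    total = sum(lengths.values())
    transcripts: list[Transcript] = []
    gene_i = 0
    for chrom, clen in lengths.items():
        n_here = max(1, round(n_genes * clen / total))
        step = clen // n_here
        for j in range(n_here):
            if gene_i >= n_genes:
                break
            gene_i += 1
            tx_start = j * step + 1200
            tx_end = min(tx_start + min(tx_length, step - 1300), clen)
            if tx_end - tx_start < 300:
                continue
            strand = "+" if gene_i % 2 else "-"
            span = tx_end - tx_start
            cds_start = tx_start + span // 6
            cds_end = tx_end - span // 6
            mid = tx_start + span // 2
            exons = ((tx_start, mid - 50), (mid + 50, tx_end))
            transcripts.append(
                Transcript(f"GENE{gene_i:04d}", chrom, strand, tx_start, tx_end,
                           cds_start, cds_end, exons)
            )
    return transcripts


def simulate_expression(
    genes: Sequence[str],
    bound_genes: Sequence[str],
    delta: float = -0.5,
    sigma: float = 0.3,
    seed: int = 0,
    replicates: int = 3,
) -> pd.DataFrame:
    """Expression table (gene, log2fc, p) with a knockdown effect.

    Unbound genes draw log2FC from Normal(0, sigma) and bound genes from
    Normal(delta, sigma); each gene's p comes from a Welch t-test on a
    simulated treatment/control replicate pair consistent with its log2FC.
    """
    bound = set(bound_genes)
    if not bound <= set(genes):
        raise ValueError("bound genes must be a subset of genes")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    mu = np.array([delta if g in bound else 0.0 for g in genes])
    log2fc = rng.normal(mu, sigma)
    n = len(genes)
    treat = rng.normal(log2fc[:, None], sigma, size=(n, replicates))
    ctrl = rng.normal(0.0, sigma, size=(n, replicates))
    from scipy import stats as _stats

    va, vb = treat.var(axis=1, ddof=1), ctrl.var(axis=1, ddof=1)
    se2 = va / replicates + vb / replicates
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (treat.mean(axis=1) - ctrl.mean(axis=1)) / np.sqrt(se2)
        df = se2**2 / (
            (va / replicates) ** 2 / (replicates - 1)
            + (vb / replicates) ** 2 / (replicates - 1)
        )
    p = np.where(se2 == 0, 1.0, 2.0 * _stats.t.sf(np.abs(t), df))
    return pd.DataFrame({"gene": genes, "log2fc": log2fc, "p": p})


@dataclass
class SimulatedStudy:
    """Everything one pipeline run needs, plus the ground truth."""

    params: SimulationParams
    genome: GenomeSequence
    truth: TruthSet
    pulldown: list[GenomicInterval]
    input_: list[GenomicInterval]
    transcripts: list[Transcript]
    expression: pd.DataFrame


def simulate_study(params: SimulationParams | None = None) -> SimulatedStudy:
    """Full fixture: genome + fragments + annotation + expression.

    Bound genes in the expression table are the transcripts whose body or
    promoter overlaps a true site, topped up with randomly chosen extra
    genes until ``n_bound_genes`` (the expression analyses are exercised at
    the study's group sizes even when few sites fall inside genes).
    """
    params = params or SimulationParams()
    genome, truth = simulate_genome(params)
    pulldown, input_ = simulate_fragments(genome, truth, params)
    transcripts = simulate_transcripts(genome, params.n_genes, seed=params.seed + 7)
    rng = np.random.default_rng(params.seed + 13)

    from .annotate_features import promoter_of  # local import avoids a cycle

    bound: set[str] = set()
    for tx in transcripts:
        prom = promoter_of(tx, genome.chrom_lengths[tx.chrom])
        for site in truth.true_sites:
            if site.overlaps(tx.interval) or site.overlaps(prom.interval):
                bound.add(tx.gene)
    all_genes = [f"GENE{i + 1:04d}" for i in range(params.n_genes)]
    extra_pool = [g for g in all_genes if g not in bound]
    target_bound = min(params.n_bound_genes, params.n_genes)
    if target_bound < params.n_bound_genes:
        log.warning("n_bound_genes clamped to n_genes (%d)", params.n_genes)
    n_extra = min(max(0, target_bound - len(bound)), len(extra_pool))
    bound |= {extra_pool[int(i)]
              for i in rng.choice(len(extra_pool), size=n_extra, replace=False)}
    expression = simulate_expression(
        all_genes, sorted(bound), params.expression_shift, params.expression_sd,
        seed=params.seed + 17, replicates=params.expression_replicates,
    )
    truth.bound_genes = sorted(bound)
    truth.true_log2fc = {
        g: (params.expression_shift if g in bound else 0.0) for g in all_genes
    }
    return SimulatedStudy(
        params, genome, truth, pulldown, input_, transcripts, expression
    )
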