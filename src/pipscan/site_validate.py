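"""Statistical validation of candidate binding sites.

A candidate motif match is accepted as a binding site only when its
differential coverage profile (unity-normalized pulldown minus input over
a +/-500 bp window) is distinguishable from null profiles built at motif
matches that were never called. For each candidate, a two-sample
Kolmogorov-Smirnov test is run against every null differential profile,
the p-values are Benjamini-Hochberg adjusted within the candidate, and the
decision p is the nearest-rank 99.9th percentile of the adjusted values:
a site is significant only when essentially all null comparisons reject.

Classes: significant (p < alpha), marginal (alpha <= p < 0.055),
nonsignificant otherwise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from math import ceil, log2
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diff_enrich import CandidateRegion
from .formats_io import CoverageTrack, GenomeSequence, GenomicInterval
from .intervals import IntervalIndex
from .motif_scan import Motif, MotifMatch, catalog_hypothetical_sites, match_motif
from .seq_reconstruct import Variant, apply_variants, backmap_match

log = logging.getLogger(__name__)


class ZeroCoverageError(ValueError):
    """Raised when a region has no coverage at all (cannot be normalized)."""


@dataclass(frozen=True)
class ValidationConfig:
    """Decision parameters for the KS validation stage.

    half_width is the decision-window half-width around a site (bp);
    percentile is the nearest-rank percentile of the BH-adjusted p-values
    used as the decision p.
    """

    alpha: float = 0.05
    marginal_upper: float = 0.055
    percentile: float = 99.9
    half_width: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < self.marginal_upper < 1):
            raise ValueError("require 0 < alpha < marginal_upper < 1")
        if not (0 < self.percentile <= 100):
            raise ValueError("percentile must be in (0, 100]")
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")

    def classify(self, p: float) -> str:
        if p < self.alpha:
            return "significant"
        if p < self.marginal_upper:
            return "marginal"
        return "nonsignificant"


@dataclass(frozen=True)
class BindingSite:
    """A motif-matched locus that went through statistical validation."""

    interval: GenomicInterval
    orientation: str
    window: GenomicInterval
    fold_log2: float
    decision_p: float
    klass: str
    indel_spanning: bool = False
    genes: tuple[str, ...] = ()
    promoters: tuple[str, ...] = ()


def unity_normalize(vector: np.ndarray) -> np.ndarray:
    """Scale per-base coverage to unit mass (sum-to-one)."""
    v = np.asarray(vector, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("expected a non-empty 1-D vector")
    if np.any(v < 0):
        raise ValueError("coverage must be non-negative")
    total = v.sum()
    if total == 0:
        raise ZeroCoverageError("zero-coverage region")
    return v / total


def differential_distribution(
    pulldown_cov: np.ndarray, input_cov: np.ndarray
) -> np.ndarray:
    """Elementwise unity(pulldown) - unity(input); always sums to zero."""
    p, i = np.asarray(pulldown_cov, float), np.asarray(input_cov, float)
    if p.shape != i.shape:
        raise ValueError("pulldown and input windows must have equal length")
    return unity_normalize(p) - unity_normalize(i)


def sample_null_regions(
    hypothetical_sites: Sequence[GenomicInterval],
    candidate_sites: Sequence[GenomicInterval],
    n: int,
    seed: int,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Two disjoint samples of n non-binding motif positions each.

    The pool is the hypothetical-site list minus every site overlapping a
    candidate (whole feature removed on any overlap); sampling is without
    replacement and reproducible under the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    index = IntervalIndex(candidate_sites) if candidate_sites else None
    pool = [
        s for s in hypothetical_sites
        if index is None or not index.overlaps(s)
    ]
    if len(pool) < 2 * n:
        raise ValueError(
            f"non-binding pool too small: {len(pool)} sites for 2n = {2 * n}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=2 * n, replace=False)
    fg = [pool[i] for i in chosen[:n]]
    bg = [pool[i] for i in chosen[n:]]
    return fg, bg


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample KS: D = sup |ECDF_x - ECDF_y|, asymptotic p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nearest_rank_percentile(values: Sequence[float], percentile: float) -> float:
    """Nearest-rank (ceiling) percentile: the ceil(q/100 * n)-th order stat."""
    v = np.sort(np.asarray(values, float))
    if len(v) == 0:
        raise ValueError("empty value list")
    # small epsilon guards against 99.9/100*1000 -> 999.0000000000001
    k = max(1, ceil(percentile / 100.0 * len(v) - 1e-9))
    return float(v[k - 1])


def decide_site(
    candidate_diff: np.ndarray,
    null_diffs: Sequence[np.ndarray],
    config: ValidationConfig,
) -> tuple[float, str]:
    """Decision p and class for one candidate differential profile."""
    if len(null_diffs) == 0:
        raise ValueError("at least one null differential distribution required")
    pvals = [ks_two_sample(candidate_diff, nd)[1] for nd in null_diffs]
    adjusted = bh_adjust(pvals)
    decision_p = nearest_rank_percentile(adjusted, config.percentile)
    return decision_p, config.classify(decision_p)


def fold_enrichment(pulldown_cov: np.ndarray, input_cov: np.ndarray) -> float:
    """log2 ratio of maximum pulldown to maximum input coverage in a window.

    When either maximum is zero, both maxima get a pseudocount of 1.
    """
    mp = float(np.max(pulldown_cov))
    mi = float(np.max(input_cov))
    if mp == 0 or mi == 0:
        mp += 1.0
        mi += 1.0
    return log2(mp / mi)


def _site_window(
    site: GenomicInterval, half_width: int, chrom_length: int
) -> GenomicInterval:
    return site.expand(half_width, chrom_length)


def build_null_differentials(
    null_fg: Sequence[GenomicInterval],
    null_bg: Sequence[GenomicInterval],
    pulldown: CoverageTrack,
    input_: CoverageTrack,
    config: ValidationConfig,
) -> list[np.ndarray]:
    """Null differential profiles from shuffled foreground/background pairs.

    Foreground windows are read from the pulldown track and background
    windows from the input track at independently sampled null sites; the
    pairing is shuffled (seeded) before subtraction. Pairs with zero
    coverage on either side are dropped with a warning.
    """
    rng = np.random.default_rng(config.seed + 1)
    order = rng.permutation(len(null_fg))
    lengths = pulldown.chrom_lengths
    diffs: list[np.ndarray] = []
    n_dropped = 0
    for fg_i, bg in zip(order, null_bg):
        fg = null_fg[int(fg_i)]
        wf = _site_window(fg, config.half_width, lengths[fg.chrom])
        wb = _site_window(bg, config.half_width, lengths[bg.chrom])
        width = min(wf.width, wb.width)
        try:
            diffs.append(
                differential_distribution(
                    pulldown.fetch(wf)[:width], input_.fetch(wb)[:width]
                )
            )
        except ZeroCoverageError:
            n_dropped += 1
    if n_dropped:
        log.warning("%d null pairs dropped for zero coverage", n_dropped)
    return diffs


def candidate_motif_sites(
    candidate_regions: Sequence[CandidateRegion],
    motif: Motif | str,
    genome: GenomeSequence,
    variants: Sequence[Variant] | None = None,
) -> list[tuple[GenomicInterval, str, bool]]:
    """Motif matches inside candidate regions, on the reconstructed sample
    sequence, back-mapped to reference coordinates and deduplicated by
    reference interval. Returns (interval, orientation, indel_spanning)."""
    motif = Motif(str(motif))
    variants = variants or []
    seen: dict[tuple[str, int, int], tuple[GenomicInterval, str, bool]] = {}
    for region in candidate_regions:
        recon = apply_variants(genome, region.interval, variants)
        for m in match_motif(recon.sequence, motif):
            ref_iv, spanning = backmap_match(
                m.interval.start, len(motif), recon
            )
            ref_iv = GenomicInterval(
                ref_iv.chrom, ref_iv.start, ref_iv.end,
                "+" if m.orientation == "forward" else "-",
            )
            key = (ref_iv.chrom, ref_iv.start, ref_iv.end)
            if key not in seen:
                seen[key] = (ref_iv, m.orientation, spanning)
    return [seen[k] for k in sorted(seen)]


def validate_sites(
    candidate_regions: Sequence[CandidateRegion],
    motif: Motif | str,
    genome: GenomeSequence,
    variants: Sequence[Variant] | None,
    pulldown: CoverageTrack,
    input_: CoverageTrack,
    config: ValidationConfig | None = None,
) -> list[BindingSite]:
    """The full validation stage: motif matches inside candidate regions
    become binding sites, each with a decision p, class, and log2 fold
    enrichment over its decision window."""
    config = config or ValidationConfig()
    if not candidate_regions:
        return []
    candidates = candidate_motif_sites(candidate_regions, motif, genome, variants)
    if not candidates:
        return []
    hypo = [
        m.interval for m in catalog_hypothetical_sites(genome, motif)
    ]
    cand_intervals = [iv for iv, _, _ in candidates]
    null_fg, null_bg = sample_null_regions(
        hypo, cand_intervals, len(candidates), config.seed
    )
    null_diffs = build_null_differentials(
        null_fg, null_bg, pulldown, input_, config
    )
    if not null_diffs:
        raise ValueError("no usable null differential distributions")
    lengths = pulldown.chrom_lengths
    sites: list[BindingSite] = []
    for iv, orientation, spanning in candidates:
        window = _site_window(iv, config.half_width, lengths[iv.chrom])
        pvec = pulldown.fetch(window)
        ivec = input_.fetch(window)
        try:
            cand_diff = differential_distribution(pvec, ivec)
        except ZeroCoverageError:
            log.warning("candidate site %s dropped: zero coverage", iv)
            continue
        decision_p, klass = decide_site(cand_diff, null_diffs, config)
        sites.append(
            BindingSite(
                interval=iv,
                orientation=orientation,
                window=window,
                fold_log2=fold_enrichment(pvec, ivec),
                decision_p=decision_p,
                klass=klass,
                indel_spanning=spanning,
            )
        )
    return sites
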