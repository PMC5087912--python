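# Methods

## Coordinate conventions and formats

Everything inside the package exchanges 0-based half-open intervals
(BED-native). The 1-based dialects of external formats (VCF POS) are
converted at the I/O boundary and nowhere else. Overlap everywhere means
at least one shared base. Readers exist for FASTA, BED3/BED6, bedGraph
(overlapping records summed, since coverage is additive), UCSC refFlat
and a minimal VCF (single alternate allele per locus; multi-allelic
records rejected with a warning). Unknown chromosomes in feature files
are skipped with a warning rather than failing, because public feature
tracks routinely include scaffolds absent from a working genome.

## Differential enrichment (sliding-window chi-square)

Fragments are used as given — no extension or shifting (fragment size 0)
— and reduced to midpoints. For a window with pulldown count a and input
count b, the 2×2 table [[a, b], [A−a, B−b]] (A, B the library totals) is
tested with the Pearson chi-square without continuity correction, 1 df.
A window with a zero margin is reported as (statistic 0, p 1). Windows
are swept at sizes {400, 600, 800, 1000, 1200} bp; the step defaults to
window/4. Significant (default p < 1e−4, uncorrected) windows with
pulldown enrichment above the library-size expectation are merged on
≥1 bp overlap; the per-size candidate lists are compiled into a union
with window-size provenance, retaining the minimal p and the counts of
the most significant contributor. This stage is deliberately permissive:
the KS validation stage is the guard against false positives, so an
uncorrected per-window threshold is a feature, not an oversight.

## Sequence reconstruction

Candidate regions are rebuilt with the sample's variants before motif
matching, as a single consensus haplotype: sorted, non-overlapping
variants with reference-verified alleles are substituted into the region.
The coordinate map sends substituted bases to their own reference
positions, inserted bases to the preceding reference base, and omits
deleted bases. A match whose reference footprint differs from the motif
length (it crosses an indel) is kept but flagged indel-spanning, since
there is no principled reason to discard a motif created by a real indel.

## Motif matching

Matching is exact-degenerate over the full IUPAC alphabet on both
strands; N in the subject never matches. Overlapping matches are all
reported, and an offset matching in both orientations yields two records;
site counting downstream deduplicates by interval, because positions, not
strand-events, are the biologically meaningful unit (both tallies are
exposed). Scrambled-motif audits permute the letters after the fixed 5'
anchor base (the alkylation-proximal thymine), uniformly and
independently per draw — the draws are with replacement across the set,
as distinctness is not required for the audit's ratio statistics.

## Statistical validation

"Unity normalization" is sum-to-one (probability-mass) normalization, so
the KS comparison of differential profiles is free of per-region scale;
max-to-one was the rejected alternative because it leaves profiles
dependent on single-base maxima. The candidate profile is
unity(pulldown) − unity(input) over the site ±500 bp. Null profiles pair
a pulldown window at one sampled null motif site with an input window at
an independently sampled null site, with a seeded shuffle of the
pairing; null sites are drawn without replacement from the hypothetical
catalog minus anything overlapping a candidate (whole feature removed on
any overlap), two disjoint samples of n each where n is the number of
candidate sites. For each candidate, one KS p per null profile is
BH-adjusted *within the candidate* (the per-candidate family reading;
a global family across candidates was the rejected alternative), and the
decision p is the nearest-rank (ceiling) 99.9th percentile of the
adjusted values — the site is accepted only if essentially every null
comparison rejects. Classes: significant p < α (0.05), marginal
α ≤ p < 0.055 (equality at α assigned to marginal so the classes are
exhaustive), else nonsignificant. Fold enrichment is
log₂(max pulldown / max input) over the decision window; when either
maximum is zero both maxima get a pseudocount of 1. Zero-coverage
regions cannot be normalized and are dropped with a warning.

## Annotation and chromatin context

Promoters are the 1000 bp upstream of the TSS on the annotated strand,
clamped at chromosome boundaries. A site carries every overlapping
transcript and promoter label (promoters are not subtracted from other
genes' bodies). Closest-feature distances are edge gaps, 0 on overlap,
ties broken toward the smaller coordinate. Consensus heterochromatin is
an endpoint sweep reporting maximal runs with per-base support ≥ k
(default 5 of 8 tracks); k = 1 reduces to the union and k = m to the
intersection, which the tests exploit. DHS position profiles use
10,000-bp bins, keeping each chromosome's final incomplete bin
normalized by its true width. Chromatin odds are within/outside site
count ratios (DHS convention) or outside/within (heterochromatin
convention).

## Expression and pathway integration

Group comparisons use Welch's unequal-variance t-test throughout, even
where a pooled test would be defensible, for robustness to unequal group
variances. The bootstrap group comparison resamples n = 100 per group
for 1000 trials and summarizes by the median Welch p — the aggregation
rule was an open choice; the median is stable and interpretable as the
typical trial. The three-criteria pathway screen tests (1) pathway genes
vs all other genes, (2) bound genes in the pathway vs all non-bound
genes, (3) bound genes in the pathway vs all other bound genes, all on
log2FC; a pathway with fewer than two bound genes (or no expressed
genes) is excluded before testing, and a candidate must pass all three
at α = 0.05. Overrepresentation uses found/expected folds and a
one-sided binomial test against the genome-wide category frequency with
Bonferroni correction (hypergeometric available as an option). Genes
with multiple expression probes collapse to the probe with the smallest
p.

## 9-mer composition

Sites overlapping a feature track are extracted with 1000-bp flanks
(2009 bp for an interior 9-bp site; clamped records flagged). K-mers are
counted per strand as given, windows containing N (masked repeats)
skipped. Because no single similarity statistic is canonical for this
comparison, three are reported — shared distinct k-mers, Jaccard over
distinct sets, and the fraction of one profile's k-mers present in the
other — with none privileged.

## Synthetic data generator

The generator emulates the study inputs at desk scale. Defaults are the
validation conditions used throughout: one 2-Mb chromosome at GC 0.41,
20 true sites and 200 decoys (concrete W-resolutions of the motif,
random orientation, ≥3 kb separation so decision windows stay disjoint),
background 0.05 fragments/bp, 8-fold enrichment at true sites,
truncated-Normal(200, 50) fragment lengths with a 50-bp floor modeling
sonication, and an expression table of 2000 genes with 200 bound genes
shifted by δ = −0.5 log2FC at noise σ = 0.3, per-gene p-values from
3-vs-3 replicate Welch tests. Enriched fragments center on their site
with Normal jitter (SD = fragment length / 4), giving unimodal peaks. In
strict mode, accidental background motif matches are rewritten (never
touching implants) until the genome-wide catalog equals the implant
list, so site counts are exact by construction. What the generator does
*not* model: read-level errors, mappability and repeat structure, GC
bias, chromatin-dependent fragmentation, and correlated gene expression
— so passing tests demonstrate the pipeline's statistical behavior under
its own assumptions, not performance on real sequencing data.

Null calibration uses 50 replicates of a scaled-down study (500 kb, 45
decoys, enrichment 1.0) so the check runs in seconds; the calibration
quantity — the rate at which unenriched motif positions are called
significant — is size-independent under the null.

## Determinism

Every stochastic step takes a seed. The pipeline derives per-stage
sub-seeds by hashing the stage name with the global seed (kept below
2³¹), so stages are individually reproducible and identical configs
yield bit-identical outputs, which the manifest's SHA-256 checksums make
checkable.

## Known limitations

The chi-square caller assumes independent fragment midpoints; overdispersion
in real libraries would inflate the permissive first stage (by design the
KS stage absorbs this). The asymptotic KS p-value is approximate for the
~1000-point profiles used. The null-profile construction assumes motif
positions outside candidate regions are representative background, which
fails if binding is pervasive. Multi-allelic loci and structural variants
are out of scope for reconstruction.
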