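"""Gene/promoter annotation, consensus heterochromatin, and chromatin odds.

Annotates validated sites with overlapping transcripts and 1000-bp
promoters, builds a >=5-of-8 consensus heterochromatin track, and reports
the within/outside chromatin ratio of the sites.
"""
import numpy as np

import pipscan as ps

params = ps.SimulationParams(genome_length=400_000, n_true_sites=8,
                             n_decoy_sites=40, n_genes=60, n_bound_genes=20,
                             seed=7)
study = ps.simulate_study(params)

sites = [
    ps.BindingSite(iv, "forward", iv.expand(500), 2.0, 0.01, "significant")
    for iv in study.truth.true_sites
]
annotated, summary = ps.annotate_sites(sites, study.transcripts,
                                       study.genome.chrom_lengths)
print("annotation summary:", summary)

rng = np.random.default_rng(0)
tracks = [
    ps.FeatureTrack([
        ps.GenomicInterval("chr1", int(s), int(s) + 2000)
        for s in rng.integers(0, 398_000, size=30)
    ])
    for _ in range(8)
]
consensus = ps.consensus_heterochromatin(tracks, k=5)
print(f"consensus heterochromatin: {len(consensus.intervals)} intervals, "
      f"{consensus.total_bp():,} bp")

dhs = ps.FeatureTrack([ps.GenomicInterval("chr1", 0, 200_000)], label="DHS")
odds = ps.chromatin_odds(annotated, dhs, "within_over_outside")
print(f"DHS within/outside odds: {odds:.2f}")
# odds near 1 mean binding is indifferent to open chromatin (sites were
# implanted uniformly here); the heterochromatin convention is outside/within
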