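import numpy as np
import pytest

from pipscan import (
    BindingSite,
    FeatureTrack,
    GenomicInterval,
    Transcript,
    annotate_sites,
    chromatin_odds,
    closest_feature_distance,
    consensus_heterochromatin,
    dhs_position_profile,
    promoter_of,
)


def make_site(chrom, start, end=None):
    iv = GenomicInterval(chrom, start, end if end is not None else start + 9)
    return BindingSite(iv, "forward", iv.expand(500), 1.0, 0.01, "significant")


def tx(gene, chrom, strand, start, end):
    return Transcript(gene, chrom, strand, start, end, start, end,
                      ((start, end),))


class TestPromoter:
    def test_plus_strand(self):
        p = promoter_of(tx("g", "chr1", "+", 5000, 9000))
        assert (p.interval.start, p.interval.end) == (4000, 5000)

    def test_minus_strand(self):
        p = promoter_of(tx("g", "chr1", "-", 4000, 8000))
        assert (p.interval.start, p.interval.end) == (8000, 9000)

    def test_clamped_at_chromosome_start(self):
        p = promoter_of(tx("g", "chr1", "+", 300, 900))
        assert (p.interval.start, p.interval.end) == (0, 300)
        assert p.interval.width == 300

    def test_clamped_at_chromosome_end(self):
        p = promoter_of(tx("g", "chr1", "-", 100, 900), chrom_length=1200)
        assert p.interval.end == 1200


class TestAnnotateSites:
    TRANSCRIPTS = [tx("GA", "chr1", "+", 5000, 9000), tx("GB", "chr1", "-", 20_000, 24_000)]

    def test_site_in_transcript_body(self):
        sites, summary = annotate_sites([make_site("chr1", 6000)], self.TRANSCRIPTS)
        assert sites[0].genes == ("GA",)
        assert sites[0].promoters == ()
        assert summary == {"in_transcript": 1, "in_promoter": 0, "intergenic": 0}

    def test_site_in_promoter_only(self):
        # GB promoter is [24000, 25000)
        sites, summary = annotate_sites([make_site("chr1", 24_100)], self.TRANSCRIPTS)
        assert sites[0].genes == ()
        assert sites[0].promoters == ("GB",)

    def test_boundary_base_half_open(self):
        # site [4995, 5004) straddles GA's promoter/TSS boundary: overlaps both
        sites, _ = annotate_sites([make_site("chr1", 4995)], self.TRANSCRIPTS)
        assert sites[0].genes == ("GA",)
        assert sites[0].promoters == ("GA",)

    def test_intergenic_sites(self):
        sites, summary = annotate_sites(
            [make_site("chr1", 100_000 + 77 * i) for i in range(10)],
            self.TRANSCRIPTS,
        )
        assert summary["intergenic"] == 10

    def test_agrees_with_all_pairs_scan(self, rng):
        transcripts = [
            tx(f"G{i}", "chr1", "+", int(s), int(s) + 2000)
            for i, s in enumerate(rng.integers(2000, 500_000, size=200))
        ]
        sites = [make_site("chr1", int(s))
                 for s in rng.integers(0, 510_000, size=300)]
        annotated, _ = annotate_sites(sites, transcripts)
        for site, out in zip(sites, annotated):
            genes = {t.gene for t in transcripts
                     if site.interval.overlaps(t.interval)}
            assert set(out.genes) == genes


class TestClosestFeature:
    TRACK = FeatureTrack([GenomicInterval("chr1", 200, 300),
                          GenomicInterval("chr1", 500, 600)], label="H3K27Ac")

    def test_overlap_is_zero(self):
        d, _ = closest_feature_distance(GenomicInterval("chr1", 250, 259), self.TRACK)
        assert d == 0

    def test_gap_between_edges(self):
        d, _ = closest_feature_distance(GenomicInterval("chr1", 100, 109), self.TRACK)
        assert d == 91  # 200 - 109

    def test_tie_prefers_smaller_coordinate(self):
        track = FeatureTrack([GenomicInterval("chr1", 0, 100),
                              GenomicInterval("chr1", 300, 400)])
        d, feature = closest_feature_distance(GenomicInterval("chr1", 150, 250), track)
        assert d == 50
        assert feature.start == 0

    def test_empty_chromosome_missing(self):
        assert closest_feature_distance(GenomicInterval("chr2", 0, 9), self.TRACK) is None

    def test_agrees_with_all_pairs_scan(self, rng):
        features = [GenomicInterval("chr1", int(s), int(s) + 50)
                    for s in rng.integers(0, 100_000, size=500)]
        track = FeatureTrack(features)
        merged = track.intervals
        for s in rng.integers(0, 100_000, size=200):
            site = GenomicInterval("chr1", int(s), int(s) + 9)
            got, _ = closest_feature_distance(site, track)
            expected = min(
                0 if site.overlaps(f) else
                (site.start - f.end if f.end <= site.start else f.start - site.end)
                for f in merged
            )
            assert got == expected


def brute_force_consensus(tracks, k, length):
    support = np.zeros(length, dtype=int)
    for t in tracks:
        mask = np.zeros(length, dtype=bool)
        for iv in t.intervals:
            mask[iv.start : iv.end] = True
        support += mask
    return support >= k


class TestConsensus:
    def _tracks(self, rng, n=8, length=100_000):
        tracks = []
        for _ in range(n):
            starts = rng.integers(0, length - 500, size=60)
            tracks.append(
                FeatureTrack([GenomicInterval("chr1", int(s), int(s) + int(w))
                              for s, w in zip(starts, rng.integers(50, 500, size=60))])
            )
        return tracks

    def test_exactly_k_included_below_excluded(self):
        base = GenomicInterval("chr1", 100, 200)
        five = [FeatureTrack([base]) for _ in range(5)]
        three = [FeatureTrack([GenomicInterval("chr1", 300, 400)]) for _ in range(3)]
        consensus = consensus_heterochromatin(five + three, k=5)
        assert consensus.overlaps(GenomicInterval("chr1", 150, 151))
        assert not consensus.overlaps(GenomicInterval("chr1", 300, 400))

    def test_matches_per_base_oracle(self, rng):
        tracks = self._tracks(rng)
        consensus = consensus_heterochromatin(tracks, k=5)
        expected = brute_force_consensus(tracks, 5, 100_000)
        got = np.zeros(100_000, dtype=bool)
        for iv in consensus.intervals:
            got[iv.start : iv.end] = True
        np.testing.assert_array_equal(got, expected)

    def test_k1_union_k8_intersection(self, rng):
        tracks = self._tracks(rng)
        union = consensus_heterochromatin(tracks, k=1)
        np.testing.assert_array_equal(
            self._mask(union), brute_force_consensus(tracks, 1, 100_000)
        )
        inter = consensus_heterochromatin(tracks, k=8)
        np.testing.assert_array_equal(
            self._mask(inter), brute_force_consensus(tracks, 8, 100_000)
        )

    @staticmethod
    def _mask(track, length=100_000):
        m = np.zeros(length, dtype=bool)
        for iv in track.intervals:
            m[iv.start : iv.end] = True
        return m

    def test_too_few_tracks_error(self):
        with pytest.raises(ValueError):
            consensus_heterochromatin([FeatureTrack([])] * 3, k=5)


class TestDhsProfile:
    def test_bin_percentages(self):
        dhs = FeatureTrack([GenomicInterval("chr1", 0, 10_000),
                            GenomicInterval("chr1", 25_000, 30_000)])
        df, flags = dhs_position_profile(
            [make_site("chr1", 5_000), make_site("chr1", 15_000)],
            dhs, {"chr1": 30_000},
        )
        assert df["dhs_pct"].tolist() == [100.0, 0.0, 50.0]
        assert flags == [True, False]

    def test_weighted_average_equals_global_coverage(self, rng):
        ivs = [GenomicInterval("chr1", int(s), int(s) + 500)
               for s in rng.integers(0, 95_000, size=40)]
        dhs = FeatureTrack(ivs)
        df, _ = dhs_position_profile([], dhs, {"chr1": 97_531})
        widths = np.minimum(df["bin_start"] + 10_000, 97_531) - df["bin_start"]
        weighted = (df["dhs_pct"] * widths).sum() / widths.sum()
        global_pct = 100.0 * dhs.total_bp("chr1") / 97_531
        assert weighted == pytest.approx(global_pct)
        assert df["dhs_pct"].between(0, 100).all()

    def test_edge_straddling_site_inside(self):
        dhs = FeatureTrack([GenomicInterval("chr1", 100, 200)])
        _, flags = dhs_position_profile([make_site("chr1", 195)], dhs, {"chr1": 1000})
        assert flags == [True]


class TestChromatinOdds:
    def test_within_over_outside(self):
        track = FeatureTrack([GenomicInterval("chr1", 0, 1000)])
        sites = [make_site("chr1", 10 * i) for i in range(20)] + [
            make_site("chr1", 2000 + 10 * i) for i in range(80)
        ]
        assert chromatin_odds(sites, track, "within_over_outside") == 0.25

    def test_all_inside_outside_mode(self):
        track = FeatureTrack([GenomicInterval("chr1", 0, 1000)])
        sites = [make_site("chr1", 10 * i) for i in range(5)]
        assert chromatin_odds(sites, track, "outside_over_within") == 0.0

    def test_zero_denominator_error(self):
        track = FeatureTrack([GenomicInterval("chr1", 0, 1000)])
        sites = [make_site("chr1", 10)]
        with pytest.raises(ValueError):
            chromatin_odds(sites, track, "within_over_outside")

    def test_uniform_sites_on_half_covered_genome(self, rng):
        length = 1_000_000
        track = FeatureTrack([GenomicInterval("chr1", 0, length // 2)])
        sites = [make_site("chr1", int(s))
                 for s in rng.integers(0, length - 9, size=4000)]
        ratio = chromatin_odds(sites, track, "within_over_outside")
        assert ratio == pytest.approx(1.0, rel=0.1)
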