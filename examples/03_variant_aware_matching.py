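"""Motif matching on reconstructed sample sequence with indel back-mapping.

A deletion in the sample creates a motif match that does not exist in the
reference; the match is found on the reconstructed sequence and its
coordinates are mapped back to the reference frame.
"""
import pipscan as ps
from pipscan import GenomicInterval, Variant

# reference almost matches TGWWGGCGW but carries an extra C
genome = ps.GenomeSequence({"chr1": "AAAA" + "TGAT" + "C" + "GGCGT" + "AAAA"})
region = GenomicInterval("chr1", 0, 18)

print("reference matches:", ps.match_motif(genome["chr1"], ps.KR12_MOTIF))

recon = ps.apply_variants(genome, region, [Variant("chr1", 7, "TC", "T")])
print("reconstructed sequence:", recon.sequence)
for m in ps.match_motif(recon.sequence, ps.KR12_MOTIF):
    ref_iv, spans_indel = ps.backmap_match(m.interval.start, 9, recon)
    print(f"match at reconstructed offset {m.interval.start} -> reference "
          f"{ref_iv} (indel-spanning: {spans_indel})")
# the reference footprint is 10 bp (one base wider than the motif) because
# the match crosses the deleted base; such sites are kept but flagged
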