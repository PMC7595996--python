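"""Build a nucleosome occupancy map and call NFRs on a synthetic locus.

Simulates a 20-kb chromosome with phased nucleosome arrays flanking
promoter NFRs, samples mononucleosome-sized MNase fragments, piles them
into per-base coverage, smooths, calls dyad axes at the peak maxima and
delineates NFRs with the 75-bp offset rule.
"""

import nucleoguide as ng

locus = ng.simulate_locus(seed=7, length=20_000)
chrom = "chr1"
dyads_truth = locus.truth_dyads[chrom]
fragments = ng.simulate_fragments(dyads_truth, chrom, locus.genome.length(chrom),
                                  fragments_per_nucleosome=30, seed=17)
profile = ng.coverage_profile(fragments, locus.genome.length(chrom))
smoothed = ng.smooth(profile, bandwidth=20)
dyads = ng.call_dyads(smoothed)
nfrs = ng.delineate_nfrs(dyads, offset=75, min_width=20)

print(f"planted nucleosomes : {len(dyads_truth)}")
print(f"called dyad axes    : {len(dyads)}")
print(f"planted NFRs        : {locus.truth_nfrs[chrom]}")
print(f"called NFRs (>=80bp): {[(n.start, n.end) for n in nfrs if n.width >= 80]}")
print("Each called NFR border sits exactly 75 bp inside its flanking dyad axis;")
print("wide called NFRs should line up with the planted promoter NFRs above.")
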