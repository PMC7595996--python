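# Methods

## Scope and coordinates

`nucleoguide` covers the computational arc from MNase-seq fragment
alignments to ranked CRISPRa guide designs and a qPCR activation
readout. Read alignment itself, duplicate marking and MNase
sequence-bias correction are out of scope: the tool consumes alignments
(SAM/BAM) or fragment intervals (BED3). All internal and emitted BED /
bedGraph coordinates are 0-based half-open; GFF3 is read and written
1-based inclusive.

## Occupancy profiles

Fragments are taken one per read pair as
[leftmost start, leftmost start + |TLEN|); single-end input can be
extended to a fixed length (default 147 bp) from the 5′ end. The default
length filter 100–200 bp keeps the mononucleosome population around
147 bp; the filter is configurable and dropped fragments are counted.
Occupancy is full-fragment per-base coverage; a fragment-midpoint
(dyad-density) estimator is provided as an alternative. Fragment
midpoints use the floor convention (start+end−1)//2 so all positions are
integers. No depth normalisation is applied by default — dyad calling
uses relative prominence and is scale-free — but mean-scaling is
available for cross-condition display.

Smoothing convolves with a Gaussian kernel (default σ = 20 bp, truncated
at 4σ) and renormalises by the in-bounds kernel mass, so interior signal
mass is conserved and edges are not damped. σ = 20 bp is small enough
that dyads ≥ 147 bp apart remain separate maxima.

## Dyad calling and NFR delineation

Dyad axes are local maxima of the smoothed profile. Plateaus take their
leftmost sample (deterministic output). Prominence is the peak height
minus the higher of the two bounding minima, each measured to the
nearest strictly higher sample or the profile edge (the same convention
as `scipy.signal.peak_prominences`, against which the implementation is
cross-checked in tests). Candidates below 5 % of the profile maximum are
suppressed; survivors are retained greedily in descending height order
subject to a 120 bp minimum separation (below the nucleosome repeat
length, above the smoothing scale). Boundary samples are never peaks.

An NFR between adjacent dyads d₁ < d₂ is the half-open interval
[d₁ + 75, d₂ − 75), emitted when its width is at least 20 bp. Under this
convention both half-open boundary coordinates sit exactly 75 bp from
their dyad axes and the width is d₂ − d₁ − 150. Whether the 75 bp offset
includes or excludes the border base is not derivable from the rule
itself; the half-open reading was chosen because it makes the border
arithmetic exact and the width formula symmetric, and it is asserted as
a type invariant. No NFR is called outside the outermost dyads (the rule
needs two flanks), and the 20 bp width floor admits ~50 bp promoter
NFRs with margin while rejecting degenerate inter-dyad gaps.

Maps from two growth conditions are compared by reciprocal overlap
(default ≥ 0.5 of both widths), paired 1-to-1 greedily by largest
overlap with leftmost tie-breaks. Mapping conditions should match the
planned activation conditions, since NFRs can be remodelled.

## Guide enumeration and off-target vetting

Protospacers are every 20-mer immediately adjacent to an NGG PAM on
either strand, with both spacer and PAM inside the queried region;
spacers containing N are excluded as unsynthesizable. Off-target burden
is computed by exact Hamming enumeration: every PAM-adjacent locus
genome-wide (both strands) is compared to the spacer and tallied into
mismatch tiers 0–3, excluding the on-target locus. Exhaustive
enumeration is deterministic, has explicit tier semantics, and is
strictly more stringent than heuristic similarity search; bulges
(indels) are not modelled. Default filter ceilings demand uniqueness at
tiers 0 and 1; tier 2–3 counts are reported for user judgment.

## Scoring and selection

The score of a candidate against a gene is

  total = 0.4·nfr + 0.4·distance + 0.2·offtarget, or 0 if crispri

* `nfr` — fraction of spacer bases inside NFRs (1 when fully inside).
* `distance` — 1 when the spacer center lies 42–210 bp upstream of the
  TSS, tapering linearly to 0 over one window width (168 bp) outside.
  The window bounds are empirical defaults from activator-walking
  experiments and are configuration, not constants; the reported
  "preferred" flag marks centers ≤ 110 bp upstream but deliberately does
  not shape the score, so the maximum is attained on the full window.
* `offtarget` — 1/(1 + Σ wₖ·tierₖ) with weights (10, 5, 1, 0.2): one
  exact off-target costs more than several distant ones, and the
  component is monotone non-increasing in every tier count.
* `crispri` — any spacer base within 30 bp upstream of the TSS or at/
  downstream of it zeroes the guide; 30 bp keeps the dCas9 footprint
  clear of the TSS. The hard zero (rather than a penalty) reflects that
  such guides risk repressing the target.

TSS distance is measured TSS → spacer floor midpoint; the floor
convention keeps distances integral and strand-symmetric conventions
consistent with the dyad-density midpoint. Component weights
(0.4/0.4/0.2) encode that chromatin accessibility and activator
geometry dominate once candidates are near-unique; they are exposed in
`RankingConfig`.

Ranking is descending by total with deterministic tie-breaks
(|TSS distance|, then + strand, then leftmost coordinate). In
bidirectional promoters one site is scored independently against both
flanking TSSs and both scores are reported; the "primary" label is only
the nominal higher-scoring gene, because observed activation of
divergent pairs is not reliably predicted by proximity. Multiplex
selection is greedy in rank order with a pairwise spacer-center spacing
of ≥ 30 bp (beyond the dCas9/sgRNA footprint); greedy was preferred over
exhaustive optimisation for transparency at the small candidate counts
involved, and an exhaustive subset oracle verifies it in tests. A
warning is issued for k = 1 requests, since single guides can fail where
combinations activate.

## Cassette output

The insert for the single-Pol-II-transcript cassette is hammerhead
ribozyme + spacer; the hammerhead is revcomp(spacer[0:6]) + a constant
catalytic core, and the HDV ribozyme plus tracrRNA scaffold are assumed
resident on the destination plasmid (the split is configurable). Oligo
pairs are the insert and its reverse complement with configurable 5′
single-stranded overhangs; an `expected_length` guard (5 nt for
Eco91I/BstEII) catches incompatible overhangs. The shipped core and HDV
sequences are the public sequences of the common cassette scheme; the
overhangs have no universal default and must be confirmed against the
user's backbone.

## qPCR readout

Technical replicates are averaged before ΔCt (standard Livak practice).
The reference Ct is the arithmetic mean of the per-reference-gene mean
Cts (default actA + benA); per-reference reporting is available via
`combine_refs="separate"` since the averaging choice is a convention.
ΔΔCt subtracts the calibrator group's mean ΔCt; folds are reported both
as the mean of per-replicate folds and as 2^(−mean ΔΔCt), because the
two summaries differ under noise and either may be wanted. Primer
efficiencies outside 90–110 % (inclusive bounds) exclude the gene with a
recorded reason. Significance is a two-sided equal-variance Student's
t test of treated vs calibrator per-replicate folds; two zero-variance
groups with equal means return p = 1 by convention.

## Synthetic data

The generator emulates the features the pipeline depends on: i.i.d.
bases at a requested GC; gene models with one divergent pair per
chromosome whose TSS separation is drawn from 260–400 bp (spanning the
~305 bp scale of compact fungal bidirectional promoters); phased dyads
at a 165 bp repeat with exact flanking dyads 75 bp outside each planted
NFR window (so the planted truth satisfies the delineation invariant by
construction), interior fills kept within ~10 % of the repeat, and
positional jitter (default σ = 5 bp for planted dyads); fragments with
centers jittered around dyads (σ = 10 bp, emulating MNase trimming
variability) and lengths N(147, 15) clipped to 100–200 bp; and Ct tables
whose treated ΔCt is the calibrator ΔCt − log₂(fold) + noise, so
noise-free tables invert exactly.

It does not emulate sequence-dependent nucleosome affinity, MNase
digestion bias, fuzzy/delocalised nucleosomes, transcription-coupled
remodelling, or read-level sequencing error. Passing recovery tests
therefore show the estimator chain is correct under phased-array
conditions, not that it is robust to every artefact of real chromatin
data.

Problem sizes: the recovery suite uses 20 kb chromosomes (~8 promoter
NFRs each) at 30 fragments per nucleosome over ten fixed seeds, a scale
at which recovery estimates stabilise while the whole suite stays fast;
oracle cross-checks run ≥ 100 randomized trials per operation on
instances up to a few kb.

## Numerical and degenerate-input choices

All-zero profiles yield no dyads (not an error). Promoter windows
clipped at chromosome ends warn rather than fail. Ranked output is
byte-deterministic for identical inputs; every CLI output avoids
timestamps and uses fixed float formatting. Seeds parameterise every
stochastic generator; identical (parameters, seed) reproduce identical
files.

## Known limitations

* Coverage-based dyad calling biases dyad positions slightly under
  asymmetric fragment overlap; borders of closely packed arrays
  (< ~150 bp dyad spacing) can merge and displace an NFR border by tens
  of bp — visible as the few misses in the recovery suite.
* No on-target activity model (e.g. sequence-based efficiency scores)
  and no Cas variants beyond NGG PAMs.
* Off-target tiers treat all mismatch positions equally; PAM-proximal
  seed mismatches are not weighted differently.
* Absolute activation magnitudes are wet-lab outcomes and are outside
  what the score predicts; the ranking orders candidates, it does not
  forecast fold change.
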