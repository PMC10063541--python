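# Methods

`nickedit` models and analyses two assays used to characterize SpCas9
nickase variants: in-vitro digestion of genomic DNA followed by WGS
(cleavage-pattern and genome-wide off-target analysis), and targeted amplicon
deep sequencing of prime-editing outcomes.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Site geometry and strand conventions

All coordinates are 0-based half-open; 1-based appears only at SAM/BED
serialization, via pysam and the BED writer.  A protospacer+PAM element at
forward-strand `start` occupies `[start, start+23)`.  SpCas9 cuts bluntly
3 bp 5′ of the NGG PAM, between protospacer bases 17|18; for a '+' element
the cut coordinate is `start+17`, for a '−' element `start+6` (the offset is
a parameter, `cut_offset`, default 3 bp from the PAM).  A blunt cut at `c`
severs the duplex between `c−1` and `c`: a severed forward strand yields a
fragment 5′ end (hence a read start) at `c`; a severed reverse strand yields
a reverse-read 5′ end at `c−1`.  The reverse-strand 5′ end is the *rightmost*
aligned base — stated explicitly because it is the most common implementation
error in this kind of caller.

Biological strand labels map through the site orientation: the non-target
strand (carrying protospacer and PAM, cleaved by RuvC) *is* the site strand;
the target strand (guide-paired, cleaved by HNH) is its opposite.  A
`DigestionModel(p_nontarget, p_target)` therefore covers the enzyme spectrum:
(1,1) wild-type nuclease, (0,1) an ideal RuvC-dead (D10A-class) nickase,
(1,0) an ideal HNH-dead non-target-strand nickase, and (1,q), 0<q<1, the
leaky HNH phenotype in which the non-target strand is always severed and the
target strand sometimes — the phenotype that turns a nominal nickase into an
occasional DSB source.

## Digestion-WGS generator

The generator emulates sequencing of purified genomic DNA digested in vitro:
random fragmentation to 400–500 bp (uniform fragment lengths, random phase
per molecule) and 150-bp single-end reads at 30× total depth (defaults; the
assay it models reports 400–500 bp fragments and 30–40× depth).  The number
of double-stranded molecule copies per contig is
`depth · mean_frag_len / (2 · read_len)`, so each strand of each copy emits
one read per ~450 bp and realized depth matches the request to within
rounding (verified to ±10% over contig interiors).

Per molecule copy, shear breakpoints are shared by the two strands (shearing
cuts the duplex); each spanned cut site then adds a strand-specific
breakpoint with its model's per-strand probability, independently per strand
and per molecule.  Every fragment 5′ end emits one error-free, perfectly
mapped read: end repair is assumed perfect (no nick translation, no
end-resection jitter) and alignment is bypassed, because for error-free
synthetic reads an external aligner adds a dependency without adding
information.  Reads are emitted directly as coordinate-sorted alignment
records; `write_sam` serializes them as valid SAM with sequences sliced from
the genome.

Not emulated: sequencing-error profiles beyond uniform substitutions (the
digestion reads are error-free; errors do not move 5′ ends), PCR duplicates,
GC bias, paired-end structure (start-position evidence is identical), or real
library chemistry.  Consequently, passing recovery tests demonstrate the
correctness of the caller's logic and calibration of its score on idealized
pileups — not robustness to mapping artifacts or duplicate-inflated starts in
real data.

Randomness: one top-level seed; child streams are derived per
(purpose, contig/site, molecule) using `numpy.random.SeedSequence` with a
CRC-32 spawn key of the tags, so outputs are byte-identical across runs and
independent of evaluation order.

## Cleavage scoring and classification

For strand s at position p, with F the number of read 5′ ends and D that
strand's coverage, the per-strand score is

    S = F² / D  (0 when D = 0),

i.e. start count × start purity.  The published scoring program for this
assay family is cited but not printed in the sources this package follows,
so this reconstruction is a design decision of the package: it is zero
without signal, grows with both evidence and uniformity, and calibrates the
conventional candidate threshold of 8.0 to ≈8 uniform starts at a fully
cleaved strand at 30–40× — reachable by genuine cuts, unreachable by shear
coincidence (F ≤ 2–3 at these depths gives S < 1).  The formula is isolated
in `strand_cleavage_score` so alternatives can be swapped in.  Two gates
suppress noise: the score is zeroed when F < `min_start_count` (default 3)
or D < `min_strand_depth` (default 10).

`est_cleaved_fraction = F/D` estimates the fraction of molecules severed on
that strand.  It is exact at q ∈ {0, 1} but biased upward at intermediate q
(≈ 3q/(1+2q) at the defaults), because a cut molecule contributes both the
start and the covering read while an uncut molecule covers the position only
with probability `read_len/mean_frag_len`.  The ±0.1 accuracy property is
therefore claimed, and tested, for q ≥ 0.9 — the regime used by the recovery
tests; treat intermediate-q values as a monotone index, not an unbiased
estimate.

Classification of a candidate cut c scores the forward strand at c and the
reverse strand at the best position in `c−1 ± pair_offset_tolerance`
(default 0: strictly blunt; the knob exists because end repair can shift
ends).  `dsb` requires **both** strands at or above the threshold — there is
deliberately no single combined score, because the phenotype of interest is
exactly the difference between both-strand and one-strand cleavage.  One
passing strand gives `nick_forward`/`nick_reverse`; neither gives `none`.

The genome-wide scan is sparse — only positions with F ≥ `min_start_count`
on either strand are classified — and equals a dense per-position
classification on small regions (tested).  Adjacent calls within 3 bp are
merged keeping the max-score position (leftmost on ties), absorbing
end-repair jitter.  Contig-terminal pileups (every molecule ends at 0 and
L−1) are excluded automatically because a classifiable cut needs `c−1 ≥ 0`
and `c ≤ L−1`.

Off-target candidates are an exhaustive both-strand scan for NGG-adjacent
20-mers within a Hamming distance of the spacer (default ≤ 6 mismatches, the
conventional candidate cutoff, paired with score ≥ 8.0 in
`filter_and_annotate`); ambiguous bases never match and are logged.  Matched
calls are annotated with protospacer, mismatch count, and the biological
strand of a nick via the site-orientation mapping above (a forward-strand
nick at a '−' site is a *target*-strand nick).

## Amplicon outcome classification

Reads are globally aligned (affine gaps: match +2, mismatch −4, gap open
−10, gap extend −1; a length-k gap costs −10−(k−1)) to both the reference
and the intended-edit allele.  The alignment engine is Biopython's
`PairwiseAligner` (C Gotoh), with a provably optimal direct path for
equal-length pairs with ≤ 3 mismatches; scores are verified in the test
suite against an independent pure-Python full-matrix DP.  Tie-breaking among
co-optimal alignments follows the aligner's deterministic enumeration order;
with these scores ties are rare and never affect scores or indel lengths.

The quantification window spans the union of the edit span (from aligning
the two alleles) and the pegRNA nick, padded ±10 bp (`window_pad`) and
clipped to the amplicon.  The window is a package design decision — the
assay's convention is not standardized — chosen to cover both places where
edits and unwanted indels arise; it is exposed as a parameter, and
`freq_indel` is non-decreasing in the pad (tested).  Labels, in precedence
order:

* `correct` — clean match to the edited allele inside the window (precedence
  over `indel` so an intended insertion/deletion is never double-counted as
  unwanted);
* `indel` — any insertion or deletion operation overlapping the window in
  the reference alignment;
* `wt` — clean match to the reference inside the window;
* `other` — substitution-only deviation from both alleles (sequencing errors
  must not inflate indel rates).

QC discards reads < 30 nt or with mean Phred < 20 when qualities are
present; frequencies are percentages of usable reads.  The PE3 two-nick
deletion statistic flags a read iff any *single* deletion operation has
length within ±`tol` (default 10, inclusive bounds) of the inter-nick
distance; split deletions are not summed, and the flag depends only on
deletion length, not position (tested).

The amplicon generator draws reads from a labelled mixture of wild-type,
correct-edit, unwanted-indel (1–10 bp insertion or deletion at the pegRNA
nick), and two-nick-deletion (length = inter-nick distance ± jitter)
outcomes, plus uniform substitution errors (default 10⁻³/base, an
Illumina-like scale).  Default mixture: 30% correct, 4.3% indel, rest wild
type — the scale of a PE3 experiment with the leaky-HNH enzyme.  Estimator
consistency is tested on error-free mixtures to isolate sampling behaviour;
with errors on, strict window matching reclassifies a small fraction of
reads (≈ window_length × error_rate) from `wt`/`correct` to `other`, a
deliberate strictness shared with window-based callers generally.

## Summary statistics

Editing purity is `100·c/(c+i)` (undefined — reported missing, never 0 or
100 — when c = i = 0).  The relative editing-purity ratio of a variant
against a reference enzyme is `(c_v/c_r)/(i_v/i_r)`.  In `summary_report`
ratios are computed per replicate against the reference's per-site mean
frequencies and then aggregated as mean ± SEM (per-site-then-aggregate
order, matching how such experiments present per-site points; the pooled
ratio-of-means is available via `ratio_mode="pooled"`).  Replicates with
zero indel frequency make the ratio infinite; they are excluded from the
mean and counted in an explicit `ratio_n_excluded` column, never imputed.
SEM uses the sample SD (n−1) over √n, undefined at n = 1.  Group comparisons
use the two-tailed unpaired Student's t-test with pooled variance
(df = n₁+n₂−2), because that is the test named by the experimental
convention this package follows; Welch's correction is available behind a
flag.  The report computes t-tests only where both groups have ≥ 3
replicates.  No multiple-testing correction is applied.

## Problem sizes used in the checks

The bundled verification uses desk-scale simulations chosen to make the
statistical properties sharp: planted-site recovery on a 1 Mb genome with 30
sites (10 per class) at 30× over 3 seeds; the leaky-HNH sweep on 50 kb at
40× (within the assay's stated 30–40× range) over q ∈ {0, 0.25, 0.5, 0.75,
1}; the off-target filter on 120 kb with planted 0/6/7-mismatch sites; and
amplicon estimators at n = 2,000 and 20,000 reads.  Genome-scale headline
counts from the real assay (hundreds of DSB sites for a wild-type nuclease,
tens for the leaky nickase) depend on the real genome and enzyme and are not
reproducible from synthetic data; the package instead verifies the
machinery's properties — exact recovery, monotonicity, calibration, and
oracle equivalence — at sizes where ground truth is known.

## Known limitations

* The cleavage score is a documented reconstruction, not the published
  program's exact formula; the 8.0 threshold is treated as a convention and
  exposed as a parameter.
* `est_cleaved_fraction` is biased at intermediate cleavage probabilities
  (see above).
* The read simulator's perfect mapping and end repair mean false-positive
  behaviour against mapping artifacts, duplicates, or repetitive sequence is
  untested by construction.
* The amplicon classifier's strict window matching undercounts slightly in
  the presence of substitution errors; `other` makes this loss visible
  rather than silently absorbing it into `wt`.
* Paired-end merging, UMIs, chimeric reads, and pegRNA scaffold
  incorporation are out of scope upstream of `quantify`.
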