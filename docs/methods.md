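# Methods

## Scope and model class

The package implements the two-phase impute-first workflow on a single
contig at desk scale. All coordinates are 0-based half-open in memory;
VCF/SAM stay 1-based on disk and conversion happens once, in the I/O
layer.

### Rough genotyping

Subsampling is per-read Bernoulli with probability
`target_coverage / input_coverage` (mates share one coin flip), so it
mirrors streaming use rather than drawing an exact count.

Pileups classify each read overlapping a site as REF-, ALT- or
other-carrying. SNVs classify by the aligned base (minimum base
quality 13, the usual pileup default). Indels classify by exact match
of the *minimal distinguishing prefix* of the two allele+context
strings, extending the context through repeat runs: this keeps the
span of evidence a read must carry symmetric between REF and ALT,
which matters when the same classifier later measures allelic balance.
Reads matching neither allele count as "other": they contribute ε to
every genotype likelihood (cancelling after renormalisation) but count
toward depth.

Genotype likelihoods use the standard biallelic mixture with a scalar
per-base error rate ε (default 0.01, matching the simulator): under
ALT dosage k, an ALT-supporting read has probability
`(1 − k/2)·ε + (k/2)·(1 − ε)`. Likelihoods are renormalised to max 0
in log10 per site. QUAL is `−10·log10 P(hom-REF | data)` under a
uniform prior — the bcftools-style "site is non-reference" confidence
— so the conventional filters (QUAL ≥ 20, DP ≤ 100) keep their usual
semantics, and hom-REF sites naturally drop out of the rough-call VCF.
Filtered sites stay available to the imputer as likelihood evidence
(configurable to withhold them instead).

### Diploid imputation

The imputer is a Li–Stephens haplotype-copying HMM over ordered pairs
of panel haplotypes:

- **Transitions.** Per interval, each copied haplotype independently
  switches with probability `p = 1 − exp(−4·Ne·d/K)` (`d` in Morgans
  from the genetic map, `K` retained haplotypes), landing uniformly.
  Default `Ne = 10,000` (human-like). The pair transition factorises,
  so one forward step is `F' = A F Aᵀ` with `A = (1−p)I + (p/K)J` —
  O(K²) per site.
- **Emissions.** Copied alleles mismatch with probability θ; the
  emission is the expectation of the site's genotype likelihood under
  the implied allele pair. Sites without read evidence take flat
  likelihoods, so their posterior comes entirely from the panel mosaic.
  θ defaults to the Li–Stephens mutation parameter
  `θ̃ / (2(θ̃ + K))` with `θ̃ = 1/Σ_{i<K} 1/i` (floored at 1e-4).
- **Decoding.** Scaled forward–backward; per-site genotype posteriors
  aggregate the two orderings of the heterozygote before the argmax
  (ties prefer more REF alleles, then 0|1 over 1|0). There is no
  sampling pass. Phase comes from the maximum-posterior ordered state
  per site, with the unordered pair oriented to keep a shared copied
  haplotype in the same slot as at the previous site — the joint
  distribution is exchangeable in the two slots, so this stitching is
  what makes the per-site argmax globally consistent.
- **State selection.** With panels larger than `k_states` (default
  32), the k haplotypes most consistent with the posterior-mean ALT
  dosage of the rough calls are retained (ties to the lower original
  index). With `k_states ≥ panel size` the HMM is exact over the full
  panel, which is what the enumeration oracle in the tests checks.
- **Chunking.** Long contigs are processed in `chunk_len` windows
  (default 20 Mb, i.e. effectively unchunked at desk scale) with
  overlap; chunk phase orientations are aligned by majority vote over
  overlapping heterozygous calls, concatenating with a warning (phase
  break) when no overlap exists.

### Personalized references

The consensus builder applies each haplotype's ALT alleles
left-to-right, first-wins on REF-span overlap (the behaviour inherited
from standard consensus tools), and records every edit as a liftover
interval (match / insertion / deletion). Reference positions inside
donor deletions map to a deleted-marker carrying the nearest left
anchor; haplotype positions inside donor insertions map back to the
insertion's left anchor, flagged inexact. The simulator builds donor
haplotypes by an independent segment-stitching code path, so
byte-identity between the two is a real cross-check, not a tautology.

The personal graph substitutes hom-ALT calls into the backbone in
place (no branching) and opens a bubble per HET: SNVs get two
single-base allele nodes (4 nodes / 4 edges per isolated SNV, hence
3k+1 nodes and 4k edges for k isolated HET SNVs); insertions keep a
one-base left anchor inside both allele nodes so neither is empty;
pure deletions use a direct flank-to-flank edge (3 nodes / 3 edges).
The two haplotype paths spell the consensus haplotypes exactly. A
pangenome comparison graph treats every panel record as a bubble,
since a graph built from the full panel VCF keeps the reference path
everywhere.

### Alignment

A minimal seed-and-extend aligner: exact k-mer seeds (k = 21, sampled
every k bases plus one flush-right seed) against a 2-bit index;
candidate diagonals ranked by seed support; each candidate extended by
an affine-gap Smith–Waterman (numba-compiled) over a window padding
the read span by the band radius (18 = (max expected indel 10 + 8)),
so alignments within the indel budget are scored exactly — the tests
verify equality with an unbanded DP. Scoring defaults: match +1,
mismatch 4, gap open 6, gap extend 1. Ties resolve to the leftmost
target position; soft clips cover unaligned read ends; every emitted
CIGAR re-scores to the reported score. MAPQ is a placeholder constant:
no implemented metric depends on multi-mapping resolution.

Diploid alignment aligns to both haplotypes and keeps the higher score
(ties → haplotype 1). For the acyclic personal graph built here this
is score-equivalent to graph alignment, because every path through the
graph follows one of the two haplotypes at each bubble.

Lift-back rewrites haplotype-frame CIGARs across liftover boundaries:
haplotype bases inside donor insertions become I ops (leading ones
become soft clips), donor deletions crossed by the alignment become D
ops, and reads lying entirely inside an insertion are dropped. The AS
score still refers to the haplotype-frame alignment.

Variant re-calling reuses the pileup+likelihood genotyper, either at
provided sites or on candidates discovered from mismatch and CIGAR-gap
evidence (≥ 2 supporting reads and ≥ 15% of local depth).

### Evaluation

- **Allele-level PR**: each diploid call is two allele calls; called
  ALT with ≥1 true ALT → TP; called REF with ≥1 true REF → TN; called
  ALT vs true hom-REF → FP; called REF vs true hom-ALT → FN. TP+FP+FN+TN
  is exactly 2 sites. **HET-level PR** scores called-HET vs truly-HET
  per site. Sites missing from the callset count as hom-REF calls
  (imputation emits every panel site, so this only affects rough-call
  evaluation). Phase is ignored here — it is what window accuracy
  measures.
- **Window accuracy**: for each panel site (pivot), the window spans
  the pivot's REF span plus 200 bp of left flank; the two
  truth-haplotype window sequences must equal the two test-haplotype
  sequences as *unordered pairs* (global haplotype labelling is
  arbitrary; local switch errors still fail). Stratified by the number
  of panel sites in the window: 1–5, 6–10, 11+. On SNV-only cohorts
  without novel alleles this is provably the same as "all genotypes
  and phases in the pivot group correct", and the tests cross-check
  the two definitions; with compensating novel differences they can
  diverge, which the per-pivot output surfaces rather than hides.
- **Allelic balance**: at each HET site, ALT-carrying /
  (ALT- + REF-carrying) overlapping reads, using the same
  symmetric-span classifier as the pileup; "other" reads are excluded
  from the denominator, zero-informative sites are excluded from
  medians and counted. Categories are signed allele-length differences
  (1-bp bins; insertions positive, deletions negative, SNVs 0).

## Simulator

The generator emulates: a phased biallelic panel (ALT frequencies
uniform on [0.05, 0.5]); a donor whose haplotypes are Li–Stephens
mosaics of the panel (per-interval switch probability
`1 − exp(−recomb_rate · distance)`) with per-site novel allele flips
recorded in the truth but invisible to the panel; and uniform
single-end error-bearing reads (forward strand only).

Defaults describe a desk-scale, human-like megabase: 60 haplotypes,
2,000 biallelic sites (20% short indels ≤ 10 bp), mosaic switch rate
5e-6/bp (≈5 switches per Mb, the posterior switch scale of a
Li–Stephens prior with Ne = 1e4 and a panel of this size), novel-flip
rate 0.01 per site per haplotype (so read evidence matters at every
coverage), 100-bp reads at 1% substitution error. The matched model
class (mosaic donor, not coalescent) makes parameter recovery a fair
test of the imputer; raising `novel_mut_rate` provides a
mismatched-model stress mode.

What the simulator does *not* emulate — and what passing tests
therefore do not show about real data: coalescent genealogies and
realistic LD decay, sequencing error profiles (indel errors, quality
ramps), paired-end and reverse-strand reads, structural variants
beyond 10 bp, multi-contig genomes, and population-scale panels.

## Experiment sizes

The canned experiments run on one CPU in minutes: the imputation-gain
grid uses a 1 Mb genome, 60-haplotype panel and 2,000 sites across
personalization coverages {0.1, 0.5, 1, 5}x; the window-strata cohort
packs 3,600 SNVs into 120 kb so all density strata are populated; the
reference-bias cohort uses 64 heterozygous sites per allele-length
category with 30x error-free 50-bp reads — short reads make alignment
end effects (the mechanism of reference bias) clearly visible at SNVs,
and 64 sites per category keep the per-category medians stable.

## Numerical and design choices

- Forward–backward uses per-site scaling; backward vectors are
  max-normalised; posterior matrices sum to 1 within 1e-9 (verified
  against exhaustive path enumeration on small instances).
- Genetic maps interpolate piecewise-linearly and extrapolate beyond
  their knots at a constant 1 cM/Mb (configurable).
- Multiallelic VCF records split into biallelic rows on read; sibling
  ALT rows of one record share a REF span legitimately, while spans
  overlapping an earlier record are dropped with a warning. Symbolic
  ALTs are rejected rather than guessed at. Panel sites overlapping
  N bases are dropped when a reference is supplied for validation.
- Output callsets are invariant under panel row permutation up to the
  documented index tie-breaks.
- Determinism: every stage is a pure function of (inputs, config,
  seed); manifests record artifact checksums.

## Known limitations

Phase decoding from marginal posteriors is exchangeable in the two
haplotype slots; the MAP-state stitching resolves it well locally but
long-range phasing degrades over stretches without heterozygous
evidence — a sampling pass would do better and is deliberately
omitted. The rough caller has no BAQ or strand-bias model. The aligner
has no paired-end rescue and a placeholder MAPQ. Variant discovery is
pileup-based; it will not assemble complex haplotypes. Window accuracy
and allelic balance are single-contig metrics here.
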