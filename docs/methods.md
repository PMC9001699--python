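# Methods

`nascentrip` re-implements, as a tested pipeline, a comparative peak-calling
and fragment-characterization workflow for RNA immunoprecipitation
sequencing (RIP-seq) of a chromatin protein (EZH2-style) against a matched
IgG mock-IP control, together with the downstream analyses that
characterize the enriched RNA fragments: gene-feature annotation,
nuclear/cytoplasmic localization from fractionated RNA-seq, and sequence
preparation for differential motif discovery.

## The peak-calling model

The caller treats the IgG control as an empirical background and asks, at
every genomic position, whether the RIP library is locally enriched beyond
what Poisson sampling of the control level would produce.

**Library matching.** Library "size" is the number of reads overlapping at
least one base of an annotated exon (the transcriptome read count). Before
any comparison, the larger library of a RIP/control pair is randomly
downsampled until its transcriptome count exactly equals the smaller one's.
The procedure is two-phase: thin the whole library at rate
`target/current` (so exonic and non-exonic reads are thinned alike), then
repair to exact equality by randomly adding back or removing
exon-overlapping reads. Exactness makes downstream counts deterministic
for a fixed seed. The transcriptome count is used *only* for matching;
peak calling runs genome-wide, because the enriched species of interest
are largely intronic and would be distorted by exon-restricted calling.

**Coverage and fold.** Per-base read counts are smoothed with a running
mean over ±`w_half` (default 150 bp; window truncated at contig edges,
divisor = actual window size). Fold enrichment at a position is
`smoothed_RIP / max(smoothed_control, lambda_min / (2*w_half + 1))`. The
floor (default `lambda_min` = 1 read per window) prevents division by an
empty control while leaving truly empty RIP regions at fold 0 — flooring
only the denominator, rather than adding a pseudocount to both tracks,
keeps the two failure modes distinct.

**Seeding.** Position *i* is a seed iff

- `fold[i] >= f_seed` (default 2.0), and
- `P(X >= k_i) <= p_max` for `X ~ Poisson(lambda_i)` (default 1e-5),

where `k_i` is the RIP window *sum* rounded half-up and
`lambda_i = max(control window sum, lambda_min)`. Window sums are the
natural integer event counts consistent with the windowed-mean coverage
definition; smoothed means would not be Poisson-scaled. The survival
function is evaluated through the regularized incomplete gamma function
(stable far into the tail); the test suite checks it against term-by-term
pmf summation to 1e-12 relative over the regime the caller uses.

**Extension and merging.** Each maximal run of seeds grows outward base by
base while `fold >= f_ext` (default 2.0); touching extensions union, so a
peak is exactly a maximal run of `fold >= f_ext` containing at least one
seed. No gap tolerance is applied — smoothing already bridges short dips.
The summit is the leftmost position of maximal fold. Peaks from the two
biological replicates whose bodies lie within `d_merge` bases (default
1000; overlap counts as distance 0) are linked, and connected components
with support from both replicates become reproducible peaks spanning the
union of their members; single-replicate peaks are discarded. Merging is
symmetric in the replicates and idempotent on its own spans.

Two presets mirror the two published operating points: `stringent`
(`f_seed` 2.0, `p_max` 1e-5) for reproducible-fragment discovery and
`replicate_track` (`f_seed` 1.7, `p_max` 1e-3) for per-replicate browser
tracks. The per-replicate preset also sets `f_ext` = 1.7, since the
extension threshold follows the seed threshold at the stringent point and
the configuration invariant requires `f_seed >= f_ext`. Tightening any of
`f_seed`, `p_max`, `f_ext` can only shrink the called position set, so the
stringent peak set is always contained in the relaxed one.

Stranded libraries are processed per strand by default (`strand_mode =
"stranded"`); `"ignore"` pools both strands for unstranded input.

## Annotation and localization

Each reproducible peak is assigned a category — coding gene, noncoding
gene, or intergenic — by overlap with (exon-flattened, per-gene) spans,
with coding genes taking precedence when a peak touches both; within the
assigned gene the feature (5'UTR / CDS / 3'UTR / intron, or noncoding
exon / intron) is decided by base-majority over the peak, with ties broken
by the precedence CDS > 5'UTR > 3'UTR > intron. Base-majority rather than
summit-only assignment is used because RIP fragments are long and a
single-position rule is brittle.

Localization uses RPM (reads per million mapped) values per fragment in
four fractionated libraries. A fragment is *nuclear* iff its nuclear RPM
strictly exceeds its cytoplasmic RPM (ties fall to cytoplasmic — the
criterion is "higher in nuclear"); nuclear fragments are *polyA−* iff
nuclear polyA− RPM strictly exceeds nuclear polyA+ RPM (ties to polyA+).
PolyA status is not assessed for cytoplasmic fragments, mirroring the
nuclear-fraction comparison that defines it. RPM cancels sequencing depth,
so calls are invariant under per-fraction depth rescaling.

## Motif-input preparation

Foreground records are the reproducible-peak sequences (minus-strand peaks
reverse-complemented); background records are each peak's upstream and
downstream flanks — by default the same length as the peak, alternatively
a fixed length — clipped at contig ends and against *all* peaks so that no
background base overlaps any foreground base (a requirement for a valid
differential background, though unstated in most protocol descriptions).
As a quantitative companion to external motif discovery, the package
reports per-set mean purine (G+A) fraction and a two-sided
label-permutation p-value (10,000 permutations, seeded, add-one
smoothed; minimum attainable p ≈ 1e-4).

## The synthetic-data generator

The generator produces the full input set — reference FASTA, GTF, four
BED read files, fraction count table — with known ground truth, under
the default study conditions:

| parameter | default | meaning |
|---|---|---|
| contig_length | 100,000 bp | single simulated contig |
| n_regions | 10 | planted enriched regions, lengths U[300, 2000] |
| enrichment_fold (φ) | 5 | multiplier on RIP read-start rate inside regions |
| read_length | 75 bp | fixed read length |
| library_sizes | 40k/32k/35k/35k | rip1/rip2/igg1/igg2; unequal to force matching |
| n_genes | 12 | alternating coding/noncoding, ± strand, ≥20% intergenic left |
| frac_table | n=1000, 89% nuclear, 75% polyA−, σ=0.5 | planted fraction labels |

Reads are placed by an inhomogeneous Poisson-type profile: a uniform
start rate on both strands, multiplied by φ inside planted regions on the
region's strand for RIP samples only, with per-sample totals fixed at the
library sizes. Genes are evenly spaced with a fixed three-exon structure;
planted regions alternate between first introns (sense strand — the
nascent-RNA situation) and intergenic gaps, with every pair of used slots
≥ ~3 kb apart so merged peaks from distinct regions cannot chain. The
fraction table draws a compartment label Bernoulli(0.89) per fragment and
a polyA label Bernoulli(0.75) for nuclear fragments; the favoured member
of each fraction pair has 4× the expected RPM, log-normal noise of s.d.
σ = 0.5 perturbs each pair's log ratio, and integer counts are Poisson
draws. Applying the noise to the pair's ratio (rather than independently
per measurement) is the definition under which the intended recovery
properties hold; Poisson count noise is small at the default mean count
(~100).

**Edge effects and the recovery measure.** Because enrichment acts on
read *starts*, enriched coverage genuinely extends one read length past a
region's end; the planted signal footprint is `[start, end +
read_length)`. Recovery of a planted region is therefore scored against
that footprint: recovered iff some reproducible peak overlaps it with both
boundaries within 150 bp (= `w_half`) of the footprint boundaries. Against
the raw start-rate interval, the end boundary of a correctly-called peak
sits systematically ~150 bp outside (74 bp read tail plus the smoothed
fold-2 crossing at φ ≈ 5), which would measure the smoothing geometry,
not recovery.

**What the generator does not emulate.** Homogeneous Poisson background
(no GC/mappability bias, no overdispersed hotspots — the model is
intentionally favourable to the caller's own test statistic), no splicing
of reads across introns, no read sequences/qualities, no transcript-level
expression structure, independent fragments in the fraction table. Passing
tests therefore demonstrate correctness of the algorithms under their own
model assumptions and calibrated specificity/sensitivity at the stated
effect sizes — not performance on real libraries with structured
background.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere; GTF is converted once at
  the I/O boundary.
- `k` rounds half-up; summit ties break leftmost; both for cross-platform
  determinism.
- Empty/all-N sequences give G/A fraction 0 with a warning; reads past the
  contig end are clipped with a warning; unstranded reads are rejected in
  stranded mode rather than silently pooled.
- All randomness (downsampling, simulation, permutation) flows from
  explicit seeds; the pipeline derives per-stage seeds from one top-level
  seed by stage-name hashing, so a stage re-run in isolation reproduces
  its behaviour in the full run.

## Problem sizes

The bundled conditions (100 kb contig, ~140k reads across four samples,
1000 fragments) run the full pipeline in a few seconds; the repeated-seed
specificity and sensitivity checks in the test suite (100 null runs, 20
recovery runs) complete in about two minutes on one CPU. These sizes were
chosen so that the planted effects are comfortably in the regime the
published thresholds target while every analysis remains interactive.

## Known limitations

- The Poisson test is applied per position with a fixed p cutoff, as
  published; no multiple-testing correction across positions is applied or
  offered.
- An IgG control is mandatory; there is no input-free background model.
- The annotator emits a single label per peak (precedence rules above); a
  peak genuinely spanning two genes is attributed to one of them.
- Replicate merging supports exactly two replicates, matching the study
  design.
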