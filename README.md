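# nascentrip

Comparative peak calling for RIP-seq (RNA immunoprecipitation sequencing)
against an IgG mock-IP control, plus the downstream analyses that
characterize the enriched RNA fragments: gene-feature annotation,
nuclear/cytoplasmic localization from fractionated RNA-seq, and
foreground/background sequence preparation for differential motif
discovery. A built-in synthetic-data generator with known ground truth
makes every stage testable end to end without any external download.

It is written for analysts working with protein–RNA interaction data of
chromatin regulators (the motivating case is EZH2/PRC2, which binds
nascent, intron-rich, non-polyadenylated RNA), where enrichment must be
called against a matched mock-IP background rather than a sequence-model
background.

## The method

For each RIP/control replicate pair, libraries are matched by randomly
downsampling the larger one until both contain the same number of
exon-overlapping ("transcriptome") reads. Per-base read counts are
smoothed with a ±150 bp running mean, and the per-position fold
enrichment is

    fold(i) = cov_RIP(i) / max(cov_IgG(i), λ_min / (2w+1))

A position seeds a peak when `fold(i) ≥ 2` **and** the Poisson upper tail
`P(X ≥ k_i) ≤ 10⁻⁵`, with `k_i` the RIP read count in the ±150 bp window
and the mean `λ_i` the control window count floored at `λ_min = 1`. Seeds
are extended base by base while `fold ≥ 2`; peaks from the two biological
replicates whose bodies lie within 1000 bp are merged into *reproducible
peaks*. A relaxed preset (`fold ≥ 1.7`, `p ≤ 10⁻³`) reproduces the
per-replicate browser-track operating point; its peak set provably
contains the stringent one.

Reproducible fragments are then annotated (coding gene / noncoding gene /
intergenic; 5'UTR / CDS / 3'UTR / noncoding exon / intron by
base-majority), classified as nuclear vs cytoplasmic and polyA+ vs polyA−
from RPM-normalized fractionated RNA-seq counts, and exported as
MEME-ready foreground/background FASTA pairs with a purine-composition
permutation test. Full model details and assumptions are in
[docs/methods.md](docs/methods.md).

## Worked example

Run the whole pipeline on a simulated dataset (100 kb contig, 10 planted
5-fold-enriched regions, two RIP and two IgG replicates with unequal
library sizes, 1000 fragments with 89% nuclear / 75% polyA− planted
fractions):

```
$ nascentrip run-all --out demo/ --seed 7 --from-simulation
done: 10 reproducible peaks; manifest at demo/manifest.json
```

All ten planted regions come back as reproducible peaks. The individual
stages can also be run on their own files:

```
$ nascentrip simulate --out sim/ --seed 5
wrote simulated dataset under sim/ (6 entries)

$ nascentrip callpeaks --rip sim/rip1.bed --rip sim/rip2.bed \
      --ctrl sim/igg1.bed --ctrl sim/igg2.bed --gtf sim/ann.gtf \
      --out peaks/ --preset stringent
replicate peaks: [13, 15]; reproducible: 10

$ nascentrip annotate --peaks peaks/reproducible_peaks.bed \
      --gtf sim/ann.gtf --out ann/
annotated 10 peaks -> ann/annotation.tsv

$ nascentrip localize --counts sim/fractions.tsv --totals sim/totals.tsv \
      --out loc/
n=1000 nuclear=0.880 polyA- among nuclear=0.739

$ nascentrip motifprep --peaks peaks/reproducible_peaks.bed \
      --fasta sim/ref.fa --out motif/
foreground=10 background=20 G/A fg=0.504 bg=0.493 p=0.083
```

Reading the numbers: the two replicates call 13 and 15 peaks individually
(a few single-replicate background fluctuations survive the per-replicate
thresholds), but exactly the 10 planted regions are supported by both
replicates within 1000 bp. The localization stage recovers the planted
fractions (88.0% nuclear against a planted 89%, 73.9% polyA− among
nuclear against 75% — binomial and classification noise at n = 1000).
The G/A report is null here (p = 0.08) because this simulation planted no
sequence bias; with `ga_bias` enabled in the simulation config the
foreground mean rises to ~0.7 and p hits the permutation floor of ~1e-4.

Every run writes a `manifest.json` recording the config echo, input
checksums, per-stage record counts and seeds; re-running with the same
seed reproduces all outputs byte-identically.

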