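"""Synthetic RIP-seq inputs with known ground truth.

The generator emulates the statistical structure the pipeline assumes:

* a reference contig of i.i.d. uniform sequence (optionally purine-biased
  inside planted regions, for motif tests);
* a toy annotation with coding genes (5'UTR/CDS/3'UTR exon structure),
  noncoding genes and >= 20% intergenic space;
* read placement by a Poisson-type process — uniform background start
  rate on both strands, multiplied by ``enrichment_fold`` inside planted
  regions (on the region's strand) for RIP samples only; per-sample
  totals are fixed at the requested library sizes, which are deliberately
  unequal to force library matching downstream;
* fragment x fraction count tables whose nuclear:cytoplasmic (and
  nuclear polyA-:polyA+) expected RPM ratio is 4:1 according to planted
  labels, with multiplicative log-normal noise on the ratio.

Everything is deterministic under a fixed seed; all randomness derives
from per-stage child seeds of ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import (
    FRACTION_COLUMNS,
    write_bed,
    write_fasta,
    write_gtf,
)
from .intervals import GeneModel, GenomicInterval, ReadAlignment

SAMPLES = ("rip1", "rip2", "igg1", "igg2")


@dataclass
class FractionTableConfig:
    n_fragments: int = 1000
    true_nuclear_fraction: float = 0.89
    true_polya_minus_fraction: float = 0.75
    noise_sigma: float = 0.5
    rpm_ratio: float = 4.0           # expected nuc:cyt (and polyA-:polyA+) ratio
    base_mean: float = 100.0         # expected counts of a fragment, pre-ratio
    totals: dict[str, int] = field(
        default_factory=lambda: {c: 1_000_000 for c in FRACTION_COLUMNS}
    )

    def __post_init__(self) -> None:
        for f in (self.true_nuclear_fraction, self.true_polya_minus_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.noise_sigma < 0 or self.rpm_ratio < 1 or self.base_mean <= 0:
            raise ValueError("invalid fraction-table parameters")


@dataclass
class SimulationConfig:
    contig_name: str = "chrSim"
    contig_length: int = 100_000
    n_regions: int = 10
    region_length_range: tuple[int, int] = (300, 2000)
    enrichment_fold: float = 5.0
    background_rate: float = 0.005   # expected read starts per base (IgG)
    read_length: int = 75
    library_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "rip1": 40_000, "rip2": 32_000, "igg1": 35_000, "igg2": 35_000,
        }
    )
    n_genes: int = 12
    ga_bias: bool = False
    frac_table: FractionTableConfig = field(default_factory=FractionTableConfig)
    seed: int = 7

    def __post_init__(self) -> None:
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be > 0")
        lo, hi = self.region_length_range
        if not 0 < lo <= hi:
            raise ValueError("bad region_length_range")
        if set(self.library_sizes) != set(SAMPLES):
            raise ValueError(f"library_sizes must have keys {SAMPLES}")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class GroundTruth:
    regions: list[GenomicInterval] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    fragment_labels: pd.DataFrame | None = None  # fragment_id, compartment, polya

    def to_dict(self) -> dict:
        out = {
            "regions": [
                {"chrom": r.chrom, "start": r.start, "end": r.end, "strand": r.strand}
                for r in self.regions
            ],
            "genes": [
                {"gene_id": g.gene_id, "biotype": g.biotype,
                 "start": g.span.start, "end": g.span.end, "strand": g.span.strand}
                for g in self.genes
            ],
        }
        if self.fragment_labels is not None:
            out["fragment_labels"] = self.fragment_labels.to_dict(orient="records")
        return out


# ---------------------------------------------------------------------------
# Layout: genes and planted regions (shared by annotation and reads)
# ---------------------------------------------------------------------------

def _build_gene(chrom: str, start: int, length: int, strand: str,
                coding: bool, gene_id: str) -> GeneModel:
    """A 3-exon gene; coding genes carry UTR/CDS structure on the exons."""
    s = start
    e1 = (s, s + 500)
    e2 = (s + 2500, s + 3000)
    e3 = (s + length - 500, s + length)
    span = GenomicInterval(chrom, s, s + length, strand)
    exons = [GenomicInterval(chrom, a, b, strand) for a, b in (e1, e2, e3)]
    if not coding:
        return GeneModel(gene_id, "noncoding", span, exons=exons)
    # terminal exons split 300 UTR / 200 CDS; orientation follows strand
    if strand == "+":
        utr5 = [GenomicInterval(chrom, e1[0], e1[0] + 300, strand)]
        cds = [
            GenomicInterval(chrom, e1[0] + 300, e1[1], strand),
            GenomicInterval(chrom, *e2, strand),
            GenomicInterval(chrom, e3[0], e3[0] + 200, strand),
        ]
        utr3 = [GenomicInterval(chrom, e3[0] + 200, e3[1], strand)]
    else:
        utr3 = [GenomicInterval(chrom, e1[0], e1[0] + 300, strand)]
        cds = [
            GenomicInterval(chrom, e1[0] + 300, e1[1], strand),
            GenomicInterval(chrom, *e2, strand),
            GenomicInterval(chrom, e3[0], e3[0] + 200, strand),
        ]
        utr5 = [GenomicInterval(chrom, e3[0] + 200, e3[1], strand)]
    return GeneModel(gene_id, "coding", span, exons=exons, cds=cds,
                     utr5=utr5, utr3=utr3)


def plan_layout(config: SimulationConfig) -> tuple[list[GeneModel], list[GenomicInterval]]:
    """Deterministic gene + planted-region layout for one configuration.

    Genes are evenly spaced (alternating coding/noncoding and +/- strand)
    leaving >= 20% of the contig intergenic.  Planted regions alternate
    between first introns (sense strand of the host gene — nascent-RNA
    style) and intergenic gaps, spaced so that merged peaks from distinct
    regions can never chain together.
    """
    rng = config.rng(0)
    chrom, L, n_genes = config.contig_name, config.contig_length, config.n_genes
    gene_len = 5500
    if n_genes * gene_len > 0.8 * L:
        raise ValueError(
            "gene layout does not fit while keeping >= 20% intergenic; "
            "reduce n_genes or enlarge the contig"
        )
    gap = (L - n_genes * gene_len) / (n_genes + 1)
    genes: list[GeneModel] = []
    starts: list[int] = []
    for i in range(n_genes):
        start = int(round(gap * (i + 1) + gene_len * i))
        starts.append(start)
        genes.append(
            _build_gene(
                chrom, start, gene_len,
                "+" if i % 2 == 0 else "-",
                coding=(i % 2 == 0),
                gene_id=f"G{i + 1:03d}_{'cod' if i % 2 == 0 else 'nc'}",
            )
        )

    # candidate slots: first introns of a mix of coding and noncoding
    # genes, plus intergenic gaps (gap j lies before gene j).  Hosts are
    # chosen so any two used slots sit >= ~3 kb apart -- farther than the
    # replicate-merge distance plus peak extension, so peaks from
    # distinct regions can never chain together.
    intron_hosts = [i for i in range(min(4, n_genes))] + list(range(6, n_genes, 2))
    intron_slots = [
        (starts[i] + 500, starts[i] + 2500, genes[i].span.strand)
        for i in intron_hosts
    ]
    gap_slots = []
    for j in range(5, n_genes, 2):
        gap_start = starts[j - 1] + gene_len
        gap_slots.append((gap_start, starts[j], None))
    slots: list[tuple[int, int, str | None]] = []
    ii = gi = 0
    while len(slots) < len(intron_slots) + len(gap_slots):
        if ii < len(intron_slots):
            slots.append(intron_slots[ii]); ii += 1
        if gi < len(gap_slots):
            slots.append(gap_slots[gi]); gi += 1
    if config.n_regions > len(slots):
        raise ValueError(
            f"cannot place {config.n_regions} regions in {len(slots)} slots; "
            "reduce n_regions or increase n_genes"
        )

    lo, hi = config.region_length_range
    regions: list[GenomicInterval] = []
    for slot_start, slot_end, slot_strand in slots[: config.n_regions]:
        usable = slot_end - slot_start - 200  # 100 bp margin each side
        length = int(min(rng.integers(lo, hi + 1), max(usable, lo)))
        offset = int(rng.integers(0, max(usable - length, 0) + 1))
        start = slot_start + 100 + offset
        strand = slot_strand or ("+" if rng.integers(2) == 0 else "-")
        regions.append(GenomicInterval(chrom, start, start + length, strand))
    regions.sort(key=lambda r: r.start)
    return genes, regions


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_reference(config: SimulationConfig,
                       regions: Sequence[GenomicInterval] | None = None) -> dict[str, str]:
    """I.i.d. uniform A/C/G/T contig; with ``ga_bias`` the G/A frequency is
    raised to 0.7 inside planted regions."""
    rng = config.rng(1)
    bases = np.array(list("ACGT"))
    probs = np.full((config.contig_length, 4), 0.25)
    if config.ga_bias:
        if regions is None:
            _, regions = plan_layout(config)
        for r in regions:
            # purine-rich on the transcribed strand: minus-strand regions
            # are pyrimidine-rich on the reference (plus) strand
            if r.strand == "-":
                probs[r.start:r.end] = [0.15, 0.35, 0.15, 0.35]  # A, C, G, T
            else:
                probs[r.start:r.end] = [0.35, 0.15, 0.35, 0.15]
    idx = np.array([rng.choice(4, p=p) for p in probs]) if config.ga_bias else \
        rng.integers(0, 4, size=config.contig_length)
    return {config.contig_name: "".join(bases[idx])}


def simulate_annotation(config: SimulationConfig) -> tuple[list[GeneModel], GroundTruth]:
    genes, regions = plan_layout(config)
    for g in genes:
        g.validate()
    return genes, GroundTruth(regions=regions, genes=genes)


def simulate_reads(config: SimulationConfig) -> tuple[dict[str, list[ReadAlignment]], GroundTruth]:
    """Four read sets (two RIP, two IgG) with planted RIP enrichment.

    Read starts follow an inhomogeneous Poisson profile — uniform on both
    strands, multiplied by ``enrichment_fold`` inside planted regions on
    the region's strand for RIP samples — scaled to the per-sample
    library sizes.
    """
    genes, regions = plan_layout(config)
    chrom = config.contig_name
    L_eff = config.contig_length - config.read_length + 1
    if L_eff <= 0:
        raise ValueError("read_length exceeds contig_length")

    base = np.full((2, L_eff), 0.5)  # rows: +, -
    enriched = base.copy()
    for r in regions:
        row = 0 if r.strand == "+" else 1
        hi = min(r.end, L_eff)
        enriched[row, r.start:hi] *= config.enrichment_fold

    read_sets: dict[str, list[ReadAlignment]] = {}
    for k, sample in enumerate(SAMPLES):
        rng = config.rng(10 + k)
        rate = enriched if sample.startswith("rip") else base
        p = (rate / rate.sum()).ravel()
        n = config.library_sizes[sample]
        counts = rng.multinomial(n, p).reshape(2, L_eff)
        reads: list[ReadAlignment] = []
        for row, strand in ((0, "+"), (1, "-")):
            positions = np.repeat(np.arange(L_eff), counts[row])
            for pos in positions:
                reads.append(
                    ReadAlignment(
                        GenomicInterval(chrom, int(pos), int(pos) + config.read_length, strand),
                        sample=sample,
                    )
                )
        reads.sort(key=lambda r: (r.interval.start, r.interval.strand == "-"))
        read_sets[sample] = reads
    return read_sets, GroundTruth(regions=regions, genes=genes)


def simulate_fraction_table(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Fragment x fraction integer count table with planted labels.

    For each fragment a compartment label is drawn Bernoulli
    (``true_nuclear_fraction``) and, for nuclear fragments, a polyA label
    Bernoulli(``true_polya_minus_fraction``).  The favoured fraction of a
    pair gets ``rpm_ratio``-fold higher expected counts; log-normal noise
    of s.d. ``noise_sigma`` perturbs each pair's log ratio, and counts
    are Poisson draws around the expectations.
    """
    fc = config.frac_table
    rng = config.rng(20)
    n = fc.n_fragments
    nuclear = rng.random(n) < fc.true_nuclear_fraction
    polya_minus = rng.random(n) < fc.true_polya_minus_fraction

    base = np.exp(rng.normal(np.log(fc.base_mean), 0.4, size=n))
    sqrt_r = np.sqrt(fc.rpm_ratio)

    def pair(favor_first: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        delta = rng.normal(0.0, fc.noise_sigma, size=n)
        ratio_half = np.where(favor_first, sqrt_r, 1.0 / sqrt_r)
        a = base * ratio_half * np.exp(delta / 2.0)
        b = base / ratio_half * np.exp(-delta / 2.0)
        return a, b

    nuc_mu, cyt_mu = pair(nuclear)
    # polyA pair is meaningful for nuclear fragments; cytoplasmic fragments
    # get an even split (their polyA columns are never assessed)
    pm_mu, pp_mu = pair(nuclear & polya_minus)

    df = pd.DataFrame({
        "fragment_id": [f"frag{i + 1:04d}" for i in range(n)],
        "nuclear": rng.poisson(nuc_mu),
        "cytoplasmic": rng.poisson(cyt_mu),
        "nuc_polyA_plus": rng.poisson(pp_mu),
        "nuc_polyA_minus": rng.poisson(pm_mu),
    })
    labels = pd.DataFrame({
        "fragment_id": df["fragment_id"],
        "compartment": np.where(nuclear, "nuclear", "cytoplasmic"),
        "polya": np.where(
            nuclear, np.where(polya_minus, "minus", "plus"), "not_assessed"
        ),
    })
    return df, GroundTruth(fragment_labels=labels)


# ---------------------------------------------------------------------------
# Ground-truth evaluation
# ---------------------------------------------------------------------------

def score_recovery(regions: Sequence[GenomicInterval], peaks: Sequence,
                   read_length: int, tolerance: int = 150) -> dict:
    """Score recovery of planted regions by called peaks.

    A planted region's *signal footprint* runs from its start to
    ``read_length`` bases past its end: enrichment acts on read starts,
    so coverage genuinely extends one read length beyond the region.  A
    region counts as recovered when some peak overlaps it and both peak
    boundaries lie within ``tolerance`` bases of the footprint
    boundaries.
    """
    recovered = []
    boundary_errors = []
    for region in regions:
        foot_start, foot_end = region.start, region.end + read_length
        hit = False
        for peak in peaks:
            iv = peak.interval if hasattr(peak, "interval") else peak
            if iv.chrom != region.chrom:
                continue
            if iv.start >= foot_end or foot_start >= iv.end:
                continue
            err_start = abs(iv.start - foot_start)
            err_end = abs(iv.end - foot_end)
            boundary_errors.append((err_start, err_end))
            if err_start <= tolerance and err_end <= tolerance:
                hit = True
        recovered.append(hit)
    return {
        "n_regions": len(regions),
        "n_recovered": int(sum(recovered)),
        "recovered": recovered,
        "boundary_errors": boundary_errors,
    }


# ---------------------------------------------------------------------------
# File-level driver
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Write ref.fa, ann.gtf, four BED files, fractions.tsv, totals.tsv and
    truth.json under ``out_dir``; returns the manifest of written paths."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes, truth = simulate_annotation(config)
    sequences = simulate_reference(config, regions=truth.regions)
    read_sets, _ = simulate_reads(config)
    frac_df, frac_truth = simulate_fraction_table(config)
    truth.fragment_labels = frac_truth.fragment_labels

    write_fasta(sequences, out / "ref.fa")
    write_gtf(genes, out / "ann.gtf")
    for sample in SAMPLES:
        write_bed(read_sets[sample], out / f"{sample}.bed")
    frac_df.to_csv(out / "fractions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [config.frac_table.totals]
    ).T.reset_index().set_axis(["fraction", "total"], axis=1).to_csv(
        out / "totals.tsv", sep="\t", index=False
    )
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
    return {
        "ref": str(out / "ref.fa"),
        "gtf": str(out / "ann.gtf"),
        "beds": {s: str(out / f"{s}.bed") for s in SAMPLES},
        "fractions": str(out / "fractions.tsv"),
        "totals": str(out / "totals.tsv"),
        "truth": str(out / "truth.json"),
    }
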