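"""Gene-context annotation and subcellular localization of enriched fragments.

Two independent analyses of a reproducible-peak set:

* *Annotation* — each peak is assigned to a coding gene, a noncoding gene
  or intergenic space, and within a gene to the feature (5'UTR / CDS /
  3'UTR / noncoding exon / intron) covering the majority of its bases.
* *Localization* — each fragment is classified as nuclear or cytoplasmic
  by comparing RPM-normalized read counts between fractionated RNA-seq
  libraries, and nuclear fragments as polyadenylated or not by comparing
  the nuclear polyA+ and polyA- fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GeneModel, GenomicInterval, ReadAlignment

CATEGORIES = ("coding_gene", "noncoding_gene", "intergenic")
CODING_FEATURES = ("cds", "utr5", "utr3", "intron")  # tie-break precedence
NONCODING_FEATURES = ("exon_nc", "intron")


@dataclass(frozen=True)
class AnnotationCall:
    category: str  # coding_gene | noncoding_gene | intergenic
    feature: str   # utr5 | cds | utr3 | exon_nc | intron | none
    gene_id: str = ""

    def __post_init__(self) -> None:
        if (self.category == "intergenic") != (self.feature == "none"):
            raise ValueError("feature 'none' iff category 'intergenic'")


@dataclass(frozen=True)
class FragmentQuant:
    """Depth-normalized (RPM) abundance of one fragment in four fractions."""

    fragment_id: str
    rpm_nuclear: float
    rpm_cytoplasmic: float
    rpm_nuc_polya_plus: float
    rpm_nuc_polya_minus: float

    def __post_init__(self) -> None:
        for v in (self.rpm_nuclear, self.rpm_cytoplasmic,
                  self.rpm_nuc_polya_plus, self.rpm_nuc_polya_minus):
            if not (v >= 0 and v == v and v != float("inf")):
                raise ValueError("RPM values must be finite and >= 0")


@dataclass(frozen=True)
class LocalizationCall:
    fragment_id: str
    compartment: str  # nuclear | cytoplasmic
    polya: str        # plus | minus | not_assessed

    def __post_init__(self) -> None:
        if self.compartment == "cytoplasmic" and self.polya != "not_assessed":
            raise ValueError("polyA status is assessed only for nuclear fragments")


# ---------------------------------------------------------------------------
# RPM and fragment quantification
# ---------------------------------------------------------------------------

def rpm(count: int, total_mapped: int) -> float:
    """Reads per million mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    return count * 1e6 / total_mapped


def quantify_fragment(fragment: GenomicInterval,
                      fraction_reads: dict[str, Sequence[ReadAlignment]],
                      totals: dict[str, int],
                      fragment_id: str = "",
                      stranded: bool = True) -> FragmentQuant:
    """Count reads overlapping the fragment (>= 1 bp) per fraction, as RPM.

    ``fraction_reads``/``totals`` are keyed nuclear, cytoplasmic,
    nuc_polyA_plus, nuc_polyA_minus.
    """
    def frac_rpm(key: str) -> float:
        n = sum(
            1 for read in fraction_reads.get(key, [])
            if fragment.overlaps(read.interval, stranded=stranded)
        )
        return rpm(n, totals[key])

    return FragmentQuant(
        fragment_id=fragment_id or f"{fragment.chrom}:{fragment.start}-{fragment.end}",
        rpm_nuclear=frac_rpm("nuclear"),
        rpm_cytoplasmic=frac_rpm("cytoplasmic"),
        rpm_nuc_polya_plus=frac_rpm("nuc_polyA_plus"),
        rpm_nuc_polya_minus=frac_rpm("nuc_polyA_minus"),
    )


def quant_from_counts(row, totals: dict[str, int]) -> FragmentQuant:
    """Build a FragmentQuant from a pre-computed count-table row."""
    return FragmentQuant(
        fragment_id=str(row["fragment_id"]),
        rpm_nuclear=rpm(int(row["nuclear"]), totals["nuclear"]),
        rpm_cytoplasmic=rpm(int(row["cytoplasmic"]), totals["cytoplasmic"]),
        rpm_nuc_polya_plus=rpm(int(row["nuc_polyA_plus"]), totals["nuc_polyA_plus"]),
        rpm_nuc_polya_minus=rpm(int(row["nuc_polyA_minus"]), totals["nuc_polyA_minus"]),
    )


# ---------------------------------------------------------------------------
# Localization classification
# ---------------------------------------------------------------------------

def classify_localization(q: FragmentQuant) -> LocalizationCall:
    """Nuclear iff strictly more RPM in the nuclear fraction; nuclear
    fragments are called polyA- iff strictly more RPM in the nuclear
    polyA- fraction.  Ties fall to cytoplasmic / polyA+ respectively."""
    if q.rpm_nuclear > q.rpm_cytoplasmic:
        polya = "minus" if q.rpm_nuc_polya_minus > q.rpm_nuc_polya_plus else "plus"
        return LocalizationCall(q.fragment_id, "nuclear", polya)
    return LocalizationCall(q.fragment_id, "cytoplasmic", "not_assessed")


def localization_summary(calls: Sequence[LocalizationCall]) -> dict:
    """Fraction nuclear and, among nuclear, fraction polyA-."""
    if not calls:
        raise ValueError("no localization calls to summarize")
    n = len(calls)
    nuclear = [c for c in calls if c.compartment == "nuclear"]
    frac_nuc = len(nuclear) / n
    frac_minus = (
        sum(1 for c in nuclear if c.polya == "minus") / len(nuclear)
        if nuclear else float("nan")
    )
    return {
        "fraction_nuclear": frac_nuc,
        "fraction_polya_minus_among_nuclear": frac_minus,
        "n": n,
    }


# ---------------------------------------------------------------------------
# Peak annotation
# ---------------------------------------------------------------------------

def _feature_overlap_bases(peak: GenomicInterval, gene: GeneModel) -> dict[str, int]:
    """Bases of the peak falling in each feature class of one gene.

    Introns are the gene-span bases not covered by any exon.  For coding
    genes, exonic bases outside annotated CDS/UTR intervals are counted
    with the CDS (they are exonic coding-gene sequence without a finer
    label; in practice the toy and GENCODE annotations partition exons).
    """
    out = {k: 0 for k in ("utr5", "cds", "utr3", "exon_nc", "intron")}
    span_ov = peak.overlap_bases(gene.span)
    if span_ov == 0:
        return out
    exonic = sum(peak.overlap_bases(e) for e in gene.exons)
    out["intron"] = span_ov - exonic
    if gene.biotype == "noncoding":
        out["exon_nc"] = exonic
        return out
    out["utr5"] = sum(peak.overlap_bases(iv) for iv in gene.utr5)
    out["utr3"] = sum(peak.overlap_bases(iv) for iv in gene.utr3)
    labelled_cds = sum(peak.overlap_bases(iv) for iv in gene.cds)
    out["cds"] = max(labelled_cds, exonic - out["utr5"] - out["utr3"])
    return out


def classify_peak(peak: GenomicInterval, genes: Sequence[GeneModel],
                  stranded: bool = False) -> AnnotationCall:
    """Assign a peak to a gene category and feature.

    Category: coding genes take precedence over noncoding when a peak
    spans both; a peak touching no gene span is intergenic.  Among genes
    of the winning biotype, the one overlapping the most peak bases is
    assigned.  Feature: base-majority within the assigned gene, ties
    broken by the precedence CDS > 5'UTR > 3'UTR > intron (noncoding:
    exon > intron).
    """
    hits = [
        g for g in genes
        if peak.overlaps(g.span, stranded=stranded)
    ]
    if not hits:
        return AnnotationCall("intergenic", "none")
    coding_hits = [g for g in hits if g.biotype == "coding"]
    pool = coding_hits or hits
    gene = max(pool, key=lambda g: (peak.overlap_bases(g.span), g.gene_id))
    ov = _feature_overlap_bases(peak, gene)
    if gene.biotype == "coding":
        order = CODING_FEATURES
        category = "coding_gene"
    else:
        order = NONCODING_FEATURES
        category = "noncoding_gene"
    feature = max(order, key=lambda f: (ov[f], -order.index(f)))
    return AnnotationCall(category, feature, gene_id=gene.gene_id)


def annotation_summary(calls: Sequence[AnnotationCall]) -> dict[str, pd.Series]:
    """Pie-chart-ready proportion tables for categories and features."""
    if not calls:
        raise ValueError("no annotation calls to summarize")
    cat = pd.Series([c.category for c in calls])
    category_props = (
        cat.value_counts(normalize=True).reindex(CATEGORIES, fill_value=0.0)
    )
    out = {"category": category_props}
    for category, feats in (
        ("coding_gene", ("utr5", "cds", "utr3", "intron")),
        ("noncoding_gene", ("exon_nc", "intron")),
    ):
        sub = [c.feature for c in calls if c.category == category]
        if sub:
            out[category] = (
                pd.Series(sub).value_counts(normalize=True)
                .reindex(feats, fill_value=0.0)
            )
    return out


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def annotation_table(peaks: Iterable, calls: Sequence[AnnotationCall]) -> pd.DataFrame:
    rows = []
    for peak, call in zip(peaks, calls):
        iv = peak.interval if hasattr(peak, "interval") else peak
        rows.append({
            "chrom": iv.chrom, "start": iv.start, "end": iv.end,
            "strand": iv.strand, "category": call.category,
            "feature": call.feature, "gene_id": call.gene_id,
        })
    return pd.DataFrame(rows)


def localization_table(quants: Sequence[FragmentQuant],
                       calls: Sequence[LocalizationCall]) -> pd.DataFrame:
    rows = []
    for q, c in zip(quants, calls):
        rows.append({
            "fragment_id": q.fragment_id,
            "rpm_nuclear": q.rpm_nuclear,
            "rpm_cytoplasmic": q.rpm_cytoplasmic,
            "rpm_nuc_polyA_plus": q.rpm_nuc_polya_plus,
            "rpm_nuc_polyA_minus": q.rpm_nuc_polya_minus,
            "compartment": c.compartment,
            "polya": c.polya,
        })
    return pd.DataFrame(rows)


def localization_scatter(quants: Sequence[FragmentQuant], path) -> None:
    """Nuclear-vs-cytoplasmic RPM scatter with the identity diagonal."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = [q.rpm_nuclear for q in quants]
    y = [q.rpm_cytoplasmic for q in quants]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=6, alpha=0.4, edgecolors="none")
    lim = max(max(x, default=1), max(y, default=1)) * 1.05
    ax.plot([0, lim], [0, lim], lw=0.8, color="grey")
    ax.set_xlabel("nuclear RPM")
    ax.set_ylabel("cytoplasmic RPM")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
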