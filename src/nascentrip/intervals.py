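"""Core genomic domain types.

All coordinates in this package are 0-based half-open ([start, end)),
matching BED/bedGraph conventions.  GTF input is converted at the I/O
boundary; nothing outside :mod:`nascentrip.genomic_io` performs a
coordinate-system conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Strand sentinel for records without strand information.
UNSTRANDED = "."

_VALID_STRANDS = frozenset({"+", "-", UNSTRANDED})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic span, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Contig name.
    start : int
        First base covered (0-based, inclusive).
    end : int
        One past the last base covered (exclusive); must exceed ``start``.
    strand : str
        ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        """True when the two intervals share >= 1 base (and strand, if asked)."""
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_bases(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance in bases between interval bodies; overlap counts as 0."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across contigs")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned sequencing read (post-alignment; mapping is upstream)."""

    interval: GenomicInterval
    sample: str = ""

    def __post_init__(self) -> None:
        # sample may legitimately be empty for anonymous fixtures, but a
        # non-empty label is required once reads enter the peak caller.
        pass


@dataclass
class GeneModel:
    """A gene flattened to unioned exons across its transcripts.

    ``cds``/``utr5``/``utr3`` are empty for noncoding genes.  Introns are
    implicit: every base of ``span`` not covered by an exon.
    """

    gene_id: str
    biotype: str  # "coding" | "noncoding"
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def validate(self) -> None:
        if self.biotype not in ("coding", "noncoding"):
            raise ValueError(f"{self.gene_id}: bad biotype {self.biotype!r}")
        for name, ivs in (
            ("exon", self.exons),
            ("CDS", self.cds),
            ("5'UTR", self.utr5),
            ("3'UTR", self.utr3),
        ):
            for iv in ivs:
                if iv.start < self.span.start or iv.end > self.span.end:
                    raise ValueError(
                        f"{self.gene_id}: {name} {iv.start}-{iv.end} outside "
                        f"gene span {self.span.start}-{self.span.end}"
                    )
        prev_end = -1
        for iv in sorted(self.exons, key=lambda e: e.start):
            if iv.start < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons after union")
            prev_end = iv.end
        if self.biotype == "coding":
            for name, ivs in (("CDS", self.cds), ("5'UTR", self.utr5), ("3'UTR", self.utr3)):
                for iv in ivs:
                    if not any(
                        iv.start >= e.start and iv.end <= e.end for e in self.exons
                    ):
                        raise ValueError(
                            f"{self.gene_id}: {name} {iv.start}-{iv.end} not "
                            "contained in any exon"
                        )

    def exonic_bases(self) -> int:
        return sum(iv.length for iv in self.exons)


@dataclass
class CoverageTrack:
    """Dense per-base numeric vector for one contig/strand.

    Carries raw counts, smoothed coverage or fold enrichment depending on
    the pipeline stage; ``values`` always has exactly ``length`` entries,
    all finite and non-negative.
    """

    contig: str
    strand: str
    values: "object"  # numpy 1-D float array

    def __post_init__(self) -> None:
        import numpy as np

        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("track values must be 1-D")
        if self.values.size and (
            not np.all(np.isfinite(self.values)) or self.values.min() < 0
        ):
            raise ValueError("track values must be finite and >= 0")

    @property
    def length(self) -> int:
        return int(self.values.size)


def union_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals into a disjoint sorted union."""
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end))
    out: list[GenomicInterval] = []
    cur = ivs[0]
    for iv in ivs[1:]:
        if iv.chrom == cur.chrom and iv.strand == cur.strand and iv.start <= cur.end:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end, cur.strand)
        else:
            out.append(cur)
            cur = iv
    out.append(cur)
    return out
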