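"""Readers and writers for the standard formats the pipeline touches.

This module is the single source of truth for coordinate conventions:
BED and bedGraph are consumed/produced verbatim (both already 0-based
half-open); GTF (1-based inclusive) is converted here and nowhere else.
"""

from __future__ import annotations

import re
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .intervals import (
    UNSTRANDED,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    ReadAlignment,
    union_intervals,
)


class ParseError(ValueError):
    """Malformed input file; message names the file and line number."""


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[ReadAlignment]:
    """Read a BED3+/BED6 file into read alignments, in file order.

    Column 4 (name), when present, becomes the sample label.  Column 6,
    when present, is the strand; records without one are unstranded.
    """
    records: list[ReadAlignment] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if not 0 <= start < end:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else UNSTRANDED
            if strand not in ("+", "-"):
                strand = UNSTRANDED
            records.append(
                ReadAlignment(GenomicInterval(chrom, start, end, strand), sample=name)
            )
    return records


def _bed_fields(item) -> tuple[GenomicInterval, str, int]:
    """Map a record onto (interval, name, score) for BED6 output.

    Peak-like objects (anything exposing ``max_fold``) get the score
    1000 * min(max_fold, 10) / 10 rounded to the nearest integer, so a
    2-fold peak scores 200 and scores saturate at 1000.
    """
    if isinstance(item, GenomicInterval):
        return item, ".", 0
    interval = item.interval
    max_fold = getattr(item, "max_fold", None)
    if max_fold is not None:
        score = int(round(1000.0 * min(float(max_fold), 10.0) / 10.0))
        name = getattr(item, "name", None) or getattr(item, "replicate", ".") or "."
        return interval, str(name), score
    return interval, getattr(item, "sample", ".") or ".", 0


def write_bed(records: Iterable, path: str | Path) -> None:
    """Write records as sorted 6-column BED."""
    rows = sorted(
        (_bed_fields(r) for r in records),
        key=lambda t: (t[0].chrom, t[0].start, t[0].end),
    )
    with open(path, "w") as fh:
        for iv, name, score in rows:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

_GTF_FEATURES = {"gene", "exon", "CDS", "five_prime_utr", "three_prime_utr"}


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read a GENCODE-dialect GTF into per-gene flattened models.

    1-based inclusive GTF coordinates become 0-based half-open.  Exons are
    unioned across transcripts of the same gene; ``gene_biotype`` (or
    ``gene_type``) ``protein_coding`` maps to coding, everything else to
    noncoding.
    """
    path = Path(path)
    spans: dict[str, GenomicInterval] = {}
    biotypes: dict[str, str] = {}
    parts: dict[str, dict[str, list[GenomicInterval]]] = defaultdict(
        lambda: defaultdict(list)
    )
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: fewer than 9 columns")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = fields[:9]
            if feature not in _GTF_FEATURES:
                continue
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            attr = _parse_attributes(attrs)
            gene_id = attr.get("gene_id")
            if not gene_id:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            iv = GenomicInterval(chrom, start, end, strand if strand in "+-" else UNSTRANDED)
            if feature == "gene":
                if gene_id not in spans:
                    order.append(gene_id)
                spans[gene_id] = iv
                bt = attr.get("gene_biotype") or attr.get("gene_type") or "noncoding"
                biotypes[gene_id] = "coding" if bt == "protein_coding" else "noncoding"
            else:
                parts[gene_id][feature].append(iv)

    genes: list[GeneModel] = []
    for gene_id in order:
        span = spans[gene_id]
        sub = parts.get(gene_id, {})
        for feat_ivs in sub.values():
            for iv in feat_ivs:
                if iv.start < span.start or iv.end > span.end:
                    raise ParseError(
                        f"{path}: gene {gene_id}: feature "
                        f"{iv.start}-{iv.end} outside gene span"
                    )
        gene = GeneModel(
            gene_id=gene_id,
            biotype=biotypes[gene_id],
            span=span,
            exons=union_intervals(sub.get("exon", [])),
            cds=union_intervals(sub.get("CDS", [])) if biotypes[gene_id] == "coding" else [],
            utr5=union_intervals(sub.get("five_prime_utr", [])) if biotypes[gene_id] == "coding" else [],
            utr3=union_intervals(sub.get("three_prime_utr", [])) if biotypes[gene_id] == "coding" else [],
        )
        gene.validate()
        genes.append(gene)
    return genes


def write_gtf(genes: Sequence[GeneModel], path: str | Path, source: str = "nascentrip") -> None:
    """Write gene models back out as GENCODE-dialect GTF (one transcript/gene)."""
    feature_map = [
        ("exons", "exon"),
        ("cds", "CDS"),
        ("utr5", "five_prime_utr"),
        ("utr3", "three_prime_utr"),
    ]
    with open(path, "w") as fh:
        for gene in genes:
            bt = "protein_coding" if gene.biotype == "coding" else "lncRNA"
            attrs = f'gene_id "{gene.gene_id}"; gene_biotype "{bt}";'
            sp = gene.span

            def line(feature: str, iv: GenomicInterval) -> str:
                return (
                    f"{iv.chrom}\t{source}\t{feature}\t{iv.start + 1}\t{iv.end}\t."
                    f"\t{sp.strand}\t.\t{attrs}\n"
                )

            fh.write(line("gene", sp))
            for attr_name, feature in feature_map:
                for iv in getattr(gene, attr_name):
                    fh.write(line(feature, iv))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as {contig: uppercase sequence}.

    The contig name is the header token before the first whitespace.
    Duplicate contig names are an error.
    """
    store: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in store:
            raise ParseError(f"{path}: duplicate contig name {record.id!r}")
        store[record.id] = str(record.seq).upper()
    return store


def write_fasta(sequences: dict[str, str] | Iterable[tuple[str, str]],
                path: str | Path, width: int = 70) -> None:
    items = sequences.items() if isinstance(sequences, dict) else sequences
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: CoverageTrack, path: str | Path, mode: str = "w") -> None:
    """Write a coverage track as run-length-encoded bedGraph.

    Adjacent equal values collapse into one interval; zero-valued runs are
    omitted.  An all-zero track therefore produces an empty file.
    """
    import numpy as np

    values = track.values
    with open(path, mode) as fh:
        if values.size == 0:
            return
        change = np.flatnonzero(np.diff(values) != 0) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [values.size]))
        for s, e in zip(starts, ends):
            v = values[s]
            if v == 0:
                continue
            out = int(v) if float(v).is_integer() else float(v)
            fh.write(f"{track.contig}\t{int(s)}\t{int(e)}\t{out}\n")


def expand_bedgraph(path: str | Path, contig: str, length: int) -> CoverageTrack:
    """Inverse of :func:`write_bedgraph` for one contig (round-trip checks)."""
    import numpy as np

    values = np.zeros(length)
    with open(path) as fh:
        for line in fh:
            c, s, e, v = line.split("\t")
            if c == contig:
                values[int(s) : int(e)] = float(v)
    return CoverageTrack(contig, UNSTRANDED, values)


# ---------------------------------------------------------------------------
# Fraction count tables
# ---------------------------------------------------------------------------

FRACTION_COLUMNS = ["nuclear", "cytoplasmic", "nuc_polyA_plus", "nuc_polyA_minus"]


def read_fraction_table(path: str | Path):
    """Read a fragment x fraction TSV of integer read counts (pandas frame)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = ["fragment_id"] + FRACTION_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df[required]


def write_fraction_table(df, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
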