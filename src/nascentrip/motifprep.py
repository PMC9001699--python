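"""Sequence preparation for differential motif discovery.

Extracts peak sequences (foreground) and their upstream/downstream flanks
(background) as MEME-ready FASTA pairs, and computes a simple G/A
composition statistic with a permutation test — a quantitative sanity
check on purine enrichment that does not replace motif discovery itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


@dataclass
class MotifPrepConfig:
    """Flank geometry for background extraction.

    ``equal_length`` gives each flank the length of its peak (the default,
    matching common differential-enrichment practice); ``fixed_length``
    uses ``fixed_flank`` bases.  Peaks shorter than ``min_peak_len`` are
    skipped.
    """

    flank_mode: str = "equal_length"
    fixed_flank: int = 500
    min_peak_len: int = 50

    def __post_init__(self) -> None:
        if self.flank_mode not in ("equal_length", "fixed_length"):
            raise ValueError("flank_mode must be 'equal_length' or 'fixed_length'")
        if self.fixed_flank <= 0 or self.min_peak_len <= 0:
            raise ValueError("fixed_flank and min_peak_len must be > 0")


def _interval_of(peak) -> GenomicInterval:
    return peak.interval if hasattr(peak, "interval") else peak


def _record_id(prefix: str, iv: GenomicInterval, name: str = "") -> str:
    label = name or prefix
    return f"{label}|{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"


def _fetch(sequences: dict[str, str], iv: GenomicInterval) -> str:
    seq = sequences[iv.chrom][iv.start:iv.end]
    if iv.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def extract_foreground(peaks: Sequence, sequences: dict[str, str],
                       config: MotifPrepConfig | None = None,
                       ) -> list[tuple[str, str]]:
    """One FASTA record per peak; minus-strand peaks reverse-complemented."""
    config = config or MotifPrepConfig()
    records: list[tuple[str, str]] = []
    for peak in peaks:
        iv = _interval_of(peak)
        if iv.chrom not in sequences:
            raise ValueError(f"peak contig {iv.chrom!r} absent from reference")
        if iv.end > len(sequences[iv.chrom]):
            raise ValueError(
                f"peak {iv.chrom}:{iv.start}-{iv.end} extends past contig end"
            )
        if iv.length < config.min_peak_len:
            logger.info(
                "skipping peak %s:%d-%d shorter than min_peak_len=%d",
                iv.chrom, iv.start, iv.end, config.min_peak_len,
            )
            continue
        name = getattr(peak, "name", "")
        records.append((_record_id("peak", iv, name), _fetch(sequences, iv)))
    return records


def extract_background(peaks: Sequence, sequences: dict[str, str],
                       config: MotifPrepConfig | None = None,
                       ) -> list[tuple[str, str]]:
    """Upstream and downstream flanks of each peak, clipped so that no
    background base overlaps any foreground peak or leaves the contig."""
    config = config or MotifPrepConfig()
    ivs = [_interval_of(p) for p in peaks]
    kept = [(p, iv) for p, iv in zip(peaks, ivs) if iv.length >= config.min_peak_len]
    by_contig: dict[str, list[GenomicInterval]] = {}
    for iv in ivs:  # clip against every peak, including short-skipped ones
        by_contig.setdefault(iv.chrom, []).append(iv)

    records: list[tuple[str, str]] = []
    for idx, (peak, iv) in enumerate(kept):
        flank_len = iv.length if config.flank_mode == "equal_length" else config.fixed_flank
        contig_len = len(sequences[iv.chrom])
        others = [o for o in by_contig[iv.chrom] if o is not iv]
        for side, lo, hi in (
            ("up", iv.start - flank_len, iv.start),
            ("down", iv.end, iv.end + flank_len),
        ):
            lo, hi = max(lo, 0), min(hi, contig_len)
            # clip against neighbouring peaks so background stays peak-free
            for o in others:
                if o.start < hi and lo < o.end:
                    if o.end <= iv.start:      # neighbour upstream
                        lo = max(lo, o.end)
                    elif o.start >= iv.end:    # neighbour downstream
                        hi = min(hi, o.start)
                    else:                      # overlapping peak bodies
                        lo, hi = 0, 0
            if hi <= lo:
                logger.info(
                    "flank %s of peak %s:%d-%d fully consumed by clipping",
                    side, iv.chrom, iv.start, iv.end,
                )
                continue
            flank = GenomicInterval(iv.chrom, lo, hi, iv.strand)
            name = getattr(peak, "name", "") or f"bg{idx + 1}"
            records.append(
                (_record_id("bg", flank, f"{name}_{side}"), _fetch(sequences, flank))
            )
    return records


def ga_fraction(sequence: str) -> float:
    """Purine (G+A) fraction of a sequence, ignoring Ns.

    All-N (or empty) sequences return 0 with a warning rather than
    dividing by zero.
    """
    seq = sequence.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"illegal characters in sequence: {sorted(bad)}")
    n_n = seq.count("N")
    denom = len(seq) - n_n
    if denom == 0:
        logger.warning("ga_fraction of all-N/empty sequence; returning 0")
        return 0.0
    return (seq.count("G") + seq.count("A")) / denom


def ga_enrichment_report(foreground: Sequence[tuple[str, str]],
                         background: Sequence[tuple[str, str]],
                         n_permutations: int = 10_000,
                         seed: int = 0) -> dict:
    """Mean G/A fraction per set plus a two-sided label-permutation p-value.

    The observed statistic is mean(foreground) - mean(background); labels
    are shuffled ``n_permutations`` times with a seeded RNG and the
    p-value is the add-one-smoothed fraction of permuted statistics at
    least as extreme in absolute value.
    """
    if not foreground or not background:
        raise ValueError("both sequence sets must be non-empty")
    fg = np.array([ga_fraction(s) for _, s in foreground])
    bg = np.array([ga_fraction(s) for _, s in background])
    observed = fg.mean() - bg.mean()

    pooled = np.concatenate([fg, bg])
    n_fg = fg.size
    rng = np.random.default_rng(seed)
    perms = rng.permuted(
        np.broadcast_to(pooled, (n_permutations, pooled.size)), axis=1
    )
    stat = perms[:, :n_fg].mean(axis=1) - perms[:, n_fg:].mean(axis=1)
    p = (np.sum(np.abs(stat) >= abs(observed) - 1e-15) + 1) / (n_permutations + 1)
    return {
        "mean_ga_foreground": float(fg.mean()),
        "mean_ga_background": float(bg.mean()),
        "difference": float(observed),
        "p_value": float(p),
        "n_foreground": int(n_fg),
        "n_background": int(bg.size),
        "n_permutations": int(n_permutations),
    }
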