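"""Comparative RIP-vs-IgG peak calling.

The algorithm, stage by stage:

1. *Library matching.*  Library size is defined as the number of reads
   overlapping annotated exons ("transcriptome reads").  The larger of a
   RIP/control pair is randomly downsampled until its transcriptome count
   exactly equals the smaller one's.
2. *Coverage.*  Per-base read counts are smoothed with a +/- ``w_half``
   (default 150 bp) running mean; the window is truncated at contig edges.
3. *Seeding.*  A position is a seed when the smoothed RIP/control fold is
   >= ``f_seed`` AND the Poisson upper tail P(X >= k) <= ``p_max``, where
   k is the RIP window sum (rounded half-up) and the mean is the control
   window sum floored at ``lambda_min``.
4. *Extension.*  Each run of seeds grows outward base by base while the
   fold stays >= ``f_ext``; overlapping extensions merge, so a peak is a
   maximal run of fold >= ``f_ext`` containing at least one seed.
5. *Reproducibility.*  Peaks from the two replicates whose bodies lie
   within ``d_merge`` bases of each other (overlap = distance 0) are
   merged into reproducible peaks; peaks supported by one replicate only
   are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import poisson as _poisson

from .intervals import (
    UNSTRANDED,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    ReadAlignment,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Threshold presets: the stringent set used for reproducible-fragment
#: discovery, and the per-replicate browser-track preset.
PRESETS = {
    "stringent": {"f_seed": 2.0, "p_max": 1e-5, "f_ext": 2.0},
    "replicate_track": {"f_seed": 1.7, "p_max": 1e-3, "f_ext": 1.7},
}


@dataclass
class PeakCallConfig:
    """All tunable parameters of the peak caller.

    Attributes
    ----------
    w_half : int
        Smoothing half-window in bases; coverage at a position is the mean
        count over +/- ``w_half``.
    f_seed : float
        Minimum fold enrichment (RIP over control) at seed positions.
    p_max : float
        Maximum Poisson upper-tail p-value at seed positions.
    f_ext : float
        Fold threshold maintained during peak extension; must not exceed
        ``f_seed``.
    d_merge : int
        Maximum body-to-body separation, in bases, for merging peaks
        across replicates.
    lambda_min : float
        Floor on the Poisson mean (control window sum), preventing
        degenerate zero-background tests.
    strand_mode : str
        ``"stranded"`` processes + and - independently; ``"ignore"`` pools
        both strands.
    seed : int
        RNG seed for library downsampling.
    """

    w_half: int = 150
    f_seed: float = 2.0
    p_max: float = 1e-5
    f_ext: float = 2.0
    d_merge: int = 1000
    lambda_min: float = 1.0
    strand_mode: str = "stranded"
    seed: int = 17

    def __post_init__(self) -> None:
        if self.w_half < 0:
            raise ValueError("w_half must be >= 0")
        if not (self.f_seed >= self.f_ext >= 1.0):
            raise ValueError("need f_seed >= f_ext >= 1")
        if not (0.0 < self.p_max < 1.0):
            raise ValueError("p_max must be in (0, 1)")
        if self.d_merge < 0:
            raise ValueError("d_merge must be >= 0")
        if self.lambda_min <= 0:
            raise ValueError("lambda_min must be > 0")
        if self.strand_mode not in ("stranded", "ignore"):
            raise ValueError("strand_mode must be 'stranded' or 'ignore'")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "PeakCallConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        params = dict(PRESETS[name])
        params.update(overrides)
        return cls(**params)

    def with_preset(self, name: str) -> "PeakCallConfig":
        return replace(self, **PRESETS[name])


@dataclass
class Peak:
    """A called enriched region from one replicate."""

    interval: GenomicInterval
    summit: int
    max_fold: float
    min_p: float
    replicate: str = ""

    def __post_init__(self) -> None:
        if not self.interval.start <= self.summit < self.interval.end:
            raise ValueError("summit outside peak interval")


@dataclass
class ReproduciblePeak:
    """Union span of cross-replicate linked peaks (>= 1 from each replicate)."""

    interval: GenomicInterval
    members: list[Peak] = field(default_factory=list)
    name: str = ""

    @property
    def max_fold(self) -> float:
        return max(p.max_fold for p in self.members)

    @property
    def min_p(self) -> float:
        return min(p.min_p for p in self.members)


# ---------------------------------------------------------------------------
# Transcriptome read counting and library matching
# ---------------------------------------------------------------------------

def _exon_cumsum(genes: Sequence[GeneModel], contig: str, strand: str,
                 length: int) -> np.ndarray:
    """Cumulative exonic-base indicator; O(1) overlap queries per read."""
    mask = np.zeros(length + 1, dtype=np.int64)
    for gene in genes:
        if gene.span.chrom != contig:
            continue
        if strand != UNSTRANDED and gene.span.strand != strand:
            continue
        for exon in gene.exons:
            mask[exon.start] += 1
            mask[min(exon.end, length)] -= 1
    covered = (np.cumsum(mask[:-1]) > 0).astype(np.int64)
    return np.concatenate(([0], np.cumsum(covered)))


def _transcriptome_flags(reads: Sequence[ReadAlignment], genes: Sequence[GeneModel],
                         strand_mode: str = "stranded") -> np.ndarray:
    """Boolean flag per read: does it overlap >= 1 exonic base?"""
    flags = np.zeros(len(reads), dtype=bool)
    if not reads or not genes:
        return flags
    by_key: dict[tuple[str, str], list[int]] = {}
    for i, read in enumerate(reads):
        iv = read.interval
        key_strand = UNSTRANDED if strand_mode == "ignore" else iv.strand
        by_key.setdefault((iv.chrom, key_strand), []).append(i)
    for (contig, strand), idx in by_key.items():
        length = max(
            max(reads[i].interval.end for i in idx),
            max(
                (g.span.end for g in genes if g.span.chrom == contig),
                default=0,
            ),
        )
        cs = _exon_cumsum(genes, contig, strand, length)
        starts = np.array([reads[i].interval.start for i in idx])
        ends = np.array([min(reads[i].interval.end, length) for i in idx])
        flags[np.asarray(idx)] = cs[ends] > cs[starts]
    return flags


def count_transcriptome_reads(reads: Sequence[ReadAlignment],
                              genes: Sequence[GeneModel],
                              strand_mode: str = "stranded") -> int:
    """Number of reads overlapping >= 1 bp of any annotated exon."""
    return int(_transcriptome_flags(reads, genes, strand_mode).sum())


def downsample_to_match(reads_large: Sequence[ReadAlignment],
                        reads_small: Sequence[ReadAlignment],
                        genes: Sequence[GeneModel],
                        seed: int = 17,
                        strand_mode: str = "stranded",
                        ) -> tuple[list[ReadAlignment], list[ReadAlignment]]:
    """Shrink the larger library to the transcriptome size of the smaller.

    Two-phase procedure: (1) sample the larger set without replacement at
    rate target/current, which thins exonic and non-exonic reads alike;
    (2) repair to exact equality of transcriptome counts by randomly
    adding back or removing exon-overlapping reads.  Deterministic for a
    fixed seed.  The smaller set is returned unchanged.
    """
    if not reads_large or not reads_small:
        raise ValueError("cannot match empty library")
    flags_large = _transcriptome_flags(reads_large, genes, strand_mode)
    n_large = int(flags_large.sum())
    target = count_transcriptome_reads(reads_small, genes, strand_mode)
    if n_large == 0 or target == 0:
        raise ValueError("cannot match empty library (zero transcriptome reads)")
    if n_large < target:
        raise ValueError(
            f"first library ({n_large} transcriptome reads) is smaller than "
            f"second ({target}); pass the larger library first"
        )
    if n_large == target:
        return list(reads_large), list(reads_small)

    rng = np.random.default_rng(seed)
    n_total = len(reads_large)
    n_keep = int(round(n_total * target / n_large))
    keep = np.zeros(n_total, dtype=bool)
    keep[rng.choice(n_total, size=n_keep, replace=False)] = True

    kept_tx = int((keep & flags_large).sum())
    if kept_tx > target:
        pool = np.flatnonzero(keep & flags_large)
        drop = rng.choice(pool, size=kept_tx - target, replace=False)
        keep[drop] = False
    elif kept_tx < target:
        pool = np.flatnonzero(~keep & flags_large)
        add = rng.choice(pool, size=target - kept_tx, replace=False)
        keep[add] = True

    downsampled = [r for r, k in zip(reads_large, keep) if k]
    return downsampled, list(reads_small)


def match_libraries(reads_a, reads_b, genes, seed: int = 17,
                    strand_mode: str = "stranded"):
    """Order-agnostic wrapper around :func:`downsample_to_match`."""
    n_a = count_transcriptome_reads(reads_a, genes, strand_mode)
    n_b = count_transcriptome_reads(reads_b, genes, strand_mode)
    if n_a >= n_b:
        big, small = downsample_to_match(reads_a, reads_b, genes, seed, strand_mode)
        return big, small
    big, small = downsample_to_match(reads_b, reads_a, genes, seed, strand_mode)
    return small, big


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

def per_base_counts(reads: Sequence[ReadAlignment], contig: str, strand: str,
                    length: int) -> CoverageTrack:
    """Per-base read-overlap counts for one contig/strand.

    ``strand='.'`` counts reads of both strands.  Reads extending past the
    contig end are clipped (with a logged warning).
    """
    delta = np.zeros(length + 1, dtype=np.int64)
    clipped = 0
    for read in reads:
        iv = read.interval
        if iv.chrom != contig:
            continue
        if strand != UNSTRANDED and iv.strand != strand:
            continue
        if iv.start >= length:
            clipped += 1
            continue
        end = iv.end
        if end > length:
            clipped += 1
            end = length
        delta[iv.start] += 1
        delta[end] -= 1
    if clipped:
        logger.warning(
            "%d read(s) extended past %s end (%d bp); clipped", clipped, contig, length
        )
    return CoverageTrack(contig, strand, np.cumsum(delta[:-1]).astype(float))


def _window_bounds(length: int, w_half: int) -> tuple[np.ndarray, np.ndarray]:
    pos = np.arange(length)
    lo = np.maximum(pos - w_half, 0)
    hi = np.minimum(pos + w_half, length - 1)
    return lo, hi


def window_sum(track: CoverageTrack, w_half: int) -> CoverageTrack:
    """Sum of raw counts over the truncated +/- ``w_half`` window."""
    if w_half < 0:
        raise ValueError("w_half must be >= 0")
    v = track.values
    if v.size == 0 or w_half == 0:
        return CoverageTrack(track.contig, track.strand, v.copy())
    cs = np.concatenate(([0.0], np.cumsum(v)))
    lo, hi = _window_bounds(v.size, w_half)
    return CoverageTrack(track.contig, track.strand, cs[hi + 1] - cs[lo])


def smooth_coverage(track: CoverageTrack, w_half: int) -> CoverageTrack:
    """Mean of counts over the truncated +/- ``w_half`` window.

    The divisor is the actual (truncated) window size, so a constant track
    stays constant right up to the contig edges.
    """
    if w_half < 0:
        raise ValueError("w_half must be >= 0")
    v = track.values
    if v.size == 0 or w_half == 0:
        return CoverageTrack(track.contig, track.strand, v.copy())
    sums = window_sum(track, w_half).values
    lo, hi = _window_bounds(v.size, w_half)
    return CoverageTrack(track.contig, track.strand, sums / (hi - lo + 1))


def fold_track(rip_smoothed: CoverageTrack, ctrl_smoothed: CoverageTrack,
               lambda_min_per_base: float) -> CoverageTrack:
    """Per-base fold enrichment with a floored control.

    The control is floored at ``lambda_min / (2 * w_half + 1)`` expressed
    per base, so regions empty in both libraries get fold 0 rather than
    0/0.
    """
    if rip_smoothed.length != ctrl_smoothed.length:
        raise ValueError("track length mismatch")
    if lambda_min_per_base <= 0:
        raise ValueError("lambda_min_per_base must be > 0")
    denom = np.maximum(ctrl_smoothed.values, lambda_min_per_base)
    return CoverageTrack(
        rip_smoothed.contig, rip_smoothed.strand, rip_smoothed.values / denom
    )


# ---------------------------------------------------------------------------
# Poisson test
# ---------------------------------------------------------------------------

def poisson_sf(k, lam):
    """Upper tail P(X >= k) for X ~ Poisson(lam).

    Evaluated through the regularized incomplete gamma function, which is
    numerically stable far into the tail.  Accepts scalars or arrays.
    """
    k_arr = np.asarray(k)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(k_arr < 0):
        raise ValueError("k must be >= 0")
    if np.any(lam_arr <= 0):
        raise ValueError("lam must be > 0")
    # P(X >= k) = sf(k - 1); sf(-1) = 1 covers k = 0.
    out = _poisson.sf(k_arr - 1, lam_arr)
    if np.isscalar(k) and np.isscalar(lam):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Seeding, extension, merging
# ---------------------------------------------------------------------------

def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def _test_arrays(rip_counts: CoverageTrack, ctrl_counts: CoverageTrack,
                 config: PeakCallConfig):
    """Window sums, fold track and the (k, lambda) Poisson operands."""
    ws_rip = window_sum(rip_counts, config.w_half)
    ws_ctrl = window_sum(ctrl_counts, config.w_half)
    sm_rip = smooth_coverage(rip_counts, config.w_half)
    sm_ctrl = smooth_coverage(ctrl_counts, config.w_half)
    lam_floor_pb = config.lambda_min / (2 * config.w_half + 1)
    fold = fold_track(sm_rip, sm_ctrl, lam_floor_pb)
    k = _round_half_up(ws_rip.values)
    lam = np.maximum(ws_ctrl.values, config.lambda_min)
    return fold, k, lam


def call_seed_sites(rip_counts: CoverageTrack, ctrl_counts: CoverageTrack,
                    config: PeakCallConfig) -> np.ndarray:
    """Positions passing both the fold and the Poisson seed criteria."""
    fold, k, lam = _test_arrays(rip_counts, ctrl_counts, config)
    return _seed_positions(fold.values, k, lam, config)


def _seed_positions(fold: np.ndarray, k: np.ndarray, lam: np.ndarray,
                    config: PeakCallConfig) -> np.ndarray:
    candidates = np.flatnonzero(fold >= config.f_seed)
    if candidates.size == 0:
        return candidates
    p = poisson_sf(k[candidates], lam[candidates])
    return candidates[p <= config.p_max]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal half-open runs of True in a boolean vector."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def extend_and_build_peaks(seed_positions: np.ndarray, fold: CoverageTrack,
                           rip_counts: CoverageTrack, ctrl_counts: CoverageTrack,
                           config: PeakCallConfig,
                           replicate_label: str = "") -> list[Peak]:
    """Grow seed runs outward while fold >= ``f_ext``; union overlaps.

    Base-by-base extension from every seed run, with unioning of touching
    extensions, is equivalent to taking each maximal run of
    fold >= ``f_ext`` that contains at least one seed — which is how it is
    computed.
    """
    fold_v = fold.values
    seeds = np.zeros(fold_v.size, dtype=bool)
    seed_positions = np.asarray(seed_positions, dtype=int)
    seeds[seed_positions] = True
    ws_rip = window_sum(rip_counts, config.w_half)
    ws_ctrl = window_sum(ctrl_counts, config.w_half)
    k = _round_half_up(ws_rip.values)
    lam = np.maximum(ws_ctrl.values, config.lambda_min)

    peaks: list[Peak] = []
    for start, end in _runs(fold_v >= config.f_ext):
        if not seeds[start:end].any():
            continue
        span = fold_v[start:end]
        summit = start + int(np.argmax(span))  # argmax -> leftmost tie
        min_p = float(np.min(poisson_sf(k[start:end], lam[start:end])))
        peaks.append(
            Peak(
                interval=GenomicInterval(fold.contig, start, end, fold.strand),
                summit=summit,
                max_fold=float(span.max()),
                min_p=min_p,
                replicate=replicate_label,
            )
        )
    return peaks


def merge_reproducible(peaks_rep1: Sequence[Peak], peaks_rep2: Sequence[Peak],
                       d_merge: int = 1000) -> list[ReproduciblePeak]:
    """Merge cross-replicate peaks whose bodies lie within ``d_merge`` bases.

    Peaks from different replicates are linked when their interval gap is
    <= ``d_merge`` (overlap counts as gap 0).  Connected components with
    support from both replicates become reproducible peaks spanning the
    union of their members; everything else is discarded.  Symmetric in
    its arguments and idempotent on its own spans.
    """
    all_peaks = list(peaks_rep1) + list(peaks_rep2)
    origin = [0] * len(peaks_rep1) + [1] * len(peaks_rep2)
    n = len(all_peaks)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def link(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(n):
        for j in range(i + 1, n):
            if origin[i] == origin[j]:
                continue
            a, b = all_peaks[i].interval, all_peaks[j].interval
            if a.chrom != b.chrom or a.strand != b.strand:
                continue
            if a.gap_to(b) <= d_merge:
                link(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    merged: list[ReproduciblePeak] = []
    for idx in groups.values():
        origins = {origin[i] for i in idx}
        if origins != {0, 1}:
            continue
        members = [all_peaks[i] for i in idx]
        iv0 = members[0].interval
        merged.append(
            ReproduciblePeak(
                interval=GenomicInterval(
                    iv0.chrom,
                    min(p.interval.start for p in members),
                    max(p.interval.end for p in members),
                    iv0.strand,
                ),
                members=sorted(members, key=lambda p: (p.interval.start, p.replicate)),
            )
        )
    merged.sort(key=lambda rp: (rp.interval.chrom, rp.interval.start, rp.interval.end))
    for i, rp in enumerate(merged, start=1):
        rp.name = f"RP{i}"
    return merged


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _contig_lengths(read_sets, genes) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for reads in read_sets:
        for read in reads:
            iv = read.interval
            lengths[iv.chrom] = max(lengths.get(iv.chrom, 0), iv.end)
    for gene in genes:
        sp = gene.span
        lengths[sp.chrom] = max(lengths.get(sp.chrom, 0), sp.end)
    return lengths


def call_peaks_pair(rip_reads: Sequence[ReadAlignment],
                    ctrl_reads: Sequence[ReadAlignment],
                    genes: Sequence[GeneModel],
                    config: PeakCallConfig,
                    replicate_label: str = "rep",
                    contig_lengths: dict[str, int] | None = None,
                    emit_tracks=None,
                    ) -> tuple[list[Peak], dict]:
    """Match one RIP/control library pair and call peaks on every
    contig/strand.  Returns the peaks and a small stats record.

    ``emit_tracks(label, strand, fold, rip_smoothed, ctrl_smoothed)``,
    when given, receives the intermediate tracks (e.g. for bedGraph
    output)."""
    if config.strand_mode == "stranded":
        unstranded = sum(
            1 for r in list(rip_reads) + list(ctrl_reads)
            if r.interval.strand == UNSTRANDED
        )
        if unstranded:
            raise ValueError(
                f"{unstranded} unstranded read(s) under strand_mode='stranded'; "
                "use strand_mode='ignore' for unstranded input"
            )
    sizes_before = (
        count_transcriptome_reads(rip_reads, genes, config.strand_mode),
        count_transcriptome_reads(ctrl_reads, genes, config.strand_mode),
    )
    rip_m, ctrl_m = match_libraries(
        rip_reads, ctrl_reads, genes, seed=config.seed,
        strand_mode=config.strand_mode,
    )
    sizes_after = (
        count_transcriptome_reads(rip_m, genes, config.strand_mode),
        count_transcriptome_reads(ctrl_m, genes, config.strand_mode),
    )
    lengths = contig_lengths or _contig_lengths([rip_m, ctrl_m], genes)
    strands = ["+", "-"] if config.strand_mode == "stranded" else [UNSTRANDED]

    peaks: list[Peak] = []
    n_seeds = 0
    for contig in sorted(lengths):
        for strand in strands:
            rip_track = per_base_counts(rip_m, contig, strand, lengths[contig])
            ctrl_track = per_base_counts(ctrl_m, contig, strand, lengths[contig])
            fold, k, lam = _test_arrays(rip_track, ctrl_track, config)
            if emit_tracks is not None:
                emit_tracks(
                    replicate_label, strand, fold,
                    smooth_coverage(rip_track, config.w_half),
                    smooth_coverage(ctrl_track, config.w_half),
                )
            seeds = _seed_positions(fold.values, k, lam, config)
            n_seeds += seeds.size
            peaks.extend(
                extend_and_build_peaks(
                    seeds, fold, rip_track, ctrl_track, config, replicate_label
                )
            )
    stats = {
        "replicate": replicate_label,
        "reads": {"rip": len(rip_reads), "ctrl": len(ctrl_reads)},
        "transcriptome_reads_before": {
            "rip": sizes_before[0], "ctrl": sizes_before[1],
        },
        "transcriptome_reads_after": {
            "rip": sizes_after[0], "ctrl": sizes_after[1],
        },
        "n_seed_positions": int(n_seeds),
        "n_peaks": len(peaks),
    }
    return peaks, stats


def call_peaks(rip_read_sets: Sequence[Sequence[ReadAlignment]],
               ctrl_read_sets: Sequence[Sequence[ReadAlignment]],
               genes: Sequence[GeneModel],
               config: PeakCallConfig | None = None,
               contig_lengths: dict[str, int] | None = None,
               emit_tracks=None,
               ):
    """Full two-replicate peak call.

    ``rip_read_sets`` and ``ctrl_read_sets`` each hold two replicates;
    replicate *i* of the RIP is matched against replicate *i* of the
    control.  Returns (per-replicate peak lists, reproducible peaks,
    run-log dict).
    """
    config = config or PeakCallConfig()
    if len(rip_read_sets) != 2 or len(ctrl_read_sets) != 2:
        raise ValueError("exactly two RIP and two control replicates required")
    per_rep: list[list[Peak]] = []
    rep_stats = []
    for i, (rip, ctrl) in enumerate(zip(rip_read_sets, ctrl_read_sets), start=1):
        peaks, stats = call_peaks_pair(
            rip, ctrl, genes, config, replicate_label=f"rep{i}",
            contig_lengths=contig_lengths, emit_tracks=emit_tracks,
        )
        per_rep.append(peaks)
        rep_stats.append(stats)
    reproducible = merge_reproducible(per_rep[0], per_rep[1], config.d_merge)
    run_log = {
        "config": {
            "w_half": config.w_half,
            "f_seed": config.f_seed,
            "p_max": config.p_max,
            "f_ext": config.f_ext,
            "d_merge": config.d_merge,
            "lambda_min": config.lambda_min,
            "strand_mode": config.strand_mode,
            "seed": config.seed,
        },
        "replicates": rep_stats,
        "n_reproducible_peaks": len(reproducible),
    }
    return per_rep, reproducible, run_log
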