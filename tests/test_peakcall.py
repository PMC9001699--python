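import math

import numpy as np
import pytest

from nascentrip.intervals import CoverageTrack, GenomicInterval, ReadAlignment
from nascentrip.peakcall import (
    Peak,
    PeakCallConfig,
    call_peaks,
    call_seed_sites,
    count_transcriptome_reads,
    downsample_to_match,
    extend_and_build_peaks,
    fold_track,
    merge_reproducible,
    per_base_counts,
    poisson_sf,
    smooth_coverage,
    window_sum,
)


def _upper_tail_by_summation(k: int, lam: float) -> float:
    """Independent oracle: sum Poisson pmf terms upward from k until they
    vanish, with log-space term evaluation."""
    total = 0.0
    i = k
    while True:
        log_term = -lam + i * math.log(lam) - math.lgamma(i + 1)
        term = math.exp(log_term)
        total += term
        if i > lam and term < total * 1e-18:
            break
        i += 1
        if i > k + 10_000:
            break
    return min(total, 1.0)


class TestPoissonSf:
    def test_k_zero_covers_whole_support(self):
        for lam in (0.01, 1.0, 50.0):
            assert poisson_sf(0, lam) == 1.0

    def test_k_one_lam_one_is_one_minus_exp_minus_one(self):
        assert poisson_sf(1, 1.0) == pytest.approx(1 - math.exp(-1), rel=1e-12)

    @pytest.mark.parametrize("lam", [0.1, 0.5, 1, 2, 5, 10, 20])
    def test_matches_termwise_summation_oracle(self, lam):
        for k in range(0, 51):
            expected = _upper_tail_by_summation(k, lam)
            assert poisson_sf(k, lam) == pytest.approx(expected, rel=1e-12)

    def test_deep_tail_value(self):
        assert poisson_sf(30, 3.0) == pytest.approx(
            _upper_tail_by_summation(30, 3.0), rel=1e-12
        )

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            poisson_sf(1, 0.0)
        with pytest.raises(ValueError):
            poisson_sf(-1, 1.0)


def _random_reads(rng, n, contig_len, read_len=50, chrom="chr1"):
    starts = rng.integers(0, contig_len - read_len, size=n)
    strands = np.where(rng.integers(0, 2, size=n) == 0, "+", "-")
    return [
        ReadAlignment(GenomicInterval(chrom, int(s), int(s) + read_len, str(st)), "r")
        for s, st in zip(starts, strands)
    ]


class TestCoverage:
    def test_single_read_unit_coverage(self):
        reads = [ReadAlignment(GenomicInterval("c", 10, 60, "+"), "r")]
        track = per_base_counts(reads, "c", "+", 100)
        assert track.values[9] == 0
        assert track.values[10] == 1 and track.values[59] == 1
        assert track.values[60] == 0

    def test_duplicate_reads_add(self):
        reads = [ReadAlignment(GenomicInterval("c", 10, 20, "+"), "r")] * 2
        track = per_base_counts(reads, "c", "+", 30)
        assert track.values[15] == 2

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(42)
        reads = _random_reads(rng, 200, 10_000)
        for strand in ("+", "-"):
            track = per_base_counts(reads, "chr1", strand, 10_000)
            brute = np.zeros(10_000)
            for pos in range(10_000):
                brute[pos] = sum(
                    1 for r in reads
                    if r.interval.strand == strand
                    and r.interval.start <= pos < r.interval.end
                )
            np.testing.assert_array_equal(track.values, brute)

    def test_read_past_contig_end_clipped(self):
        reads = [ReadAlignment(GenomicInterval("c", 90, 120, "+"), "r")]
        track = per_base_counts(reads, "c", "+", 100)
        assert track.values[99] == 1
        assert track.values.sum() == 10


class TestSmoothing:
    def test_constant_track_unchanged(self):
        track = CoverageTrack("c", "+", np.full(500, 3.0))
        out = smooth_coverage(track, 150)
        np.testing.assert_allclose(out.values, 3.0)

    def test_zero_half_window_is_identity(self):
        values = np.arange(10.0)
        out = smooth_coverage(CoverageTrack("c", "+", values), 0)
        np.testing.assert_array_equal(out.values, values)

    def test_point_mass_spreads_over_full_window(self):
        values = np.zeros(2000)
        values[1000] = 1.0
        out = smooth_coverage(CoverageTrack("c", "+", values), 150)
        inside = out.values[850:1151]
        np.testing.assert_allclose(inside, 1 / 301)
        assert out.values[849] == 0 and out.values[1151] == 0

    def test_smoothing_matches_brute_force_window_mean(self):
        rng = np.random.default_rng(7)
        reads = _random_reads(rng, 200, 10_000)
        track = per_base_counts(reads, "chr1", "+", 10_000)
        out = smooth_coverage(track, 150)
        for pos in rng.integers(0, 10_000, size=50):
            lo, hi = max(0, pos - 150), min(9999, pos + 150)
            assert out.values[pos] == pytest.approx(
                track.values[lo : hi + 1].mean(), rel=1e-12
            )

    def test_window_sum_equals_mean_times_size_in_interior(self):
        rng = np.random.default_rng(3)
        values = rng.poisson(2.0, size=3000).astype(float)
        track = CoverageTrack("c", "+", values)
        sums = window_sum(track, 150).values
        means = smooth_coverage(track, 150).values
        np.testing.assert_allclose(sums[150:-150], means[150:-150] * 301, rtol=1e-12)

    def test_window_sum_of_zero_track_is_zero(self):
        out = window_sum(CoverageTrack("c", "+", np.zeros(100)), 10)
        assert out.values.sum() == 0


class TestFoldTrack:
    def test_simple_ratio(self):
        rip = CoverageTrack("c", "+", [4.0])
        ctrl = CoverageTrack("c", "+", [2.0])
        assert fold_track(rip, ctrl, 0.001).values[0] == pytest.approx(2.0)

    def test_zero_control_floored(self):
        rip = CoverageTrack("c", "+", [1.0])
        ctrl = CoverageTrack("c", "+", [0.0])
        # floor = lambda_min / (2 * 150 + 1) with lambda_min = 1
        out = fold_track(rip, ctrl, 1 / 301)
        assert out.values[0] == pytest.approx(301.0)

    def test_zero_rip_gives_zero_fold(self):
        rip = CoverageTrack("c", "+", np.zeros(10))
        ctrl = CoverageTrack("c", "+", np.zeros(10))
        assert fold_track(rip, ctrl, 0.5).values.sum() == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            fold_track(
                CoverageTrack("c", "+", [1.0]),
                CoverageTrack("c", "+", [1.0, 2.0]),
                0.1,
            )


class TestSeeding:
    def test_empty_tracks_give_no_seeds(self):
        z = CoverageTrack("c", "+", np.zeros(1000))
        assert call_seed_sites(z, z, PeakCallConfig()).size == 0

    def test_planted_region_interior_is_all_seeds(self):
        rng = np.random.default_rng(5)
        L = 20_000
        rip = rng.poisson(0.5, L).astype(float)
        ctrl = rng.poisson(0.5, L).astype(float)
        rip[8000:10000] = rng.poisson(2.5, 2000)  # 5-fold enrichment
        seeds = call_seed_sites(
            CoverageTrack("c", "+", rip), CoverageTrack("c", "+", ctrl),
            PeakCallConfig(),
        )
        interior = np.arange(8150, 9850)
        assert np.isin(interior, seeds).all()

    def test_fold_passing_but_insignificant_count_is_not_seed(self):
        """Both conditions are required: a 3-fold site whose window count
        is too small for p <= 1e-5 must not seed."""
        L = 1000
        rip = np.zeros(L)
        ctrl = np.zeros(L)
        rip[500:503] = 2.0  # window sum 6, fold ~ 3 vs floored control
        ctrl[500:503] = 0.6
        config = PeakCallConfig(lambda_min=2.0)
        fold_ok = 6.0 / 2.0 >= config.f_seed
        assert fold_ok and poisson_sf(6, 2.0) > config.p_max
        assert call_seed_sites(
            CoverageTrack("c", "+", rip), CoverageTrack("c", "+", ctrl), config
        ).size == 0


class TestExtension:
    def _tracks(self, fold_values):
        fold = CoverageTrack("c", "+", fold_values)
        zero = CoverageTrack("c", "+", np.ones(len(fold_values)))
        return fold, zero

    def test_manual_trace_of_extension_rule(self):
        fold, counts = self._tracks([1.0, 2.5, 3.0, 2.2, 1.5])
        (peak,) = extend_and_build_peaks(
            np.array([2]), fold, counts, counts, PeakCallConfig(w_half=0), "rep1"
        )
        assert (peak.interval.start, peak.interval.end) == (1, 4)
        assert peak.summit == 2
        assert peak.max_fold == pytest.approx(3.0)

    def test_touching_extensions_union_into_one_peak(self):
        fold, counts = self._tracks([1.0, 2.5, 2.1, 2.4, 2.2, 2.6, 1.0])
        peaks = extend_and_build_peaks(
            np.array([1, 5]), fold, counts, counts, PeakCallConfig(w_half=0), "r"
        )
        assert len(peaks) == 1
        assert (peaks[0].interval.start, peaks[0].interval.end) == (1, 6)

    def test_isolated_seed_gives_single_base_peak(self):
        fold, counts = self._tracks([1.0, 1.0, 5.0, 1.0])
        (peak,) = extend_and_build_peaks(
            np.array([2]), fold, counts, counts, PeakCallConfig(w_half=0), "r"
        )
        assert peak.interval.length == 1
        assert peak.summit == 2

    def test_run_without_seed_is_not_a_peak(self):
        fold, counts = self._tracks([2.5, 2.5, 1.0, 2.5, 2.5])
        peaks = extend_and_build_peaks(
            np.array([0]), fold, counts, counts, PeakCallConfig(w_half=0), "r"
        )
        assert len(peaks) == 1
        assert peaks[0].interval.end == 2

    def test_summit_tie_breaks_leftmost(self):
        fold, counts = self._tracks([1.0, 3.0, 3.0, 1.0])
        (peak,) = extend_and_build_peaks(
            np.array([1, 2]), fold, counts, counts, PeakCallConfig(w_half=0), "r"
        )
        assert peak.summit == 1


def _peak(start, end, rep, strand="+"):
    return Peak(GenomicInterval("c", start, end, strand), start, 3.0, 1e-9, rep)


class TestMergeReproducible:
    def test_gap_within_threshold_merges(self):
        merged = merge_reproducible(
            [_peak(100, 200, "rep1")], [_peak(1150, 1300, "rep2")], 1000
        )
        assert len(merged) == 1
        assert (merged[0].interval.start, merged[0].interval.end) == (100, 1300)

    def test_gap_beyond_threshold_does_not_merge(self):
        merged = merge_reproducible(
            [_peak(100, 200, "rep1")], [_peak(1300, 1400, "rep2")], 1000
        )
        assert merged == []

    def test_single_replicate_peaks_discarded(self):
        assert merge_reproducible([_peak(0, 10, "rep1")], [], 1000) == []

    def test_identical_peaks_merge_to_same_span_and_symmetry(self):
        a = [_peak(100, 200, "rep1"), _peak(5000, 5100, "rep1")]
        b = [_peak(120, 210, "rep2"), _peak(5050, 5200, "rep2")]
        m1 = merge_reproducible(a, b, 1000)
        m2 = merge_reproducible(b, a, 1000)
        assert [
            (m.interval.start, m.interval.end) for m in m1
        ] == [(100, 210), (5000, 5200)]
        assert [(m.interval.start, m.interval.end) for m in m1] == [
            (m.interval.start, m.interval.end) for m in m2
        ]

    def test_idempotent_on_own_output_spans(self):
        a = [_peak(100, 200, "rep1")]
        b = [_peak(300, 400, "rep2")]
        m = merge_reproducible(a, b, 1000)
        again = merge_reproducible(
            [_peak(m[0].interval.start, m[0].interval.end, "rep1")],
            [_peak(m[0].interval.start, m[0].interval.end, "rep2")],
            1000,
        )
        assert (again[0].interval.start, again[0].interval.end) == (
            m[0].interval.start, m[0].interval.end,
        )

    def test_different_strands_never_merge(self):
        merged = merge_reproducible(
            [_peak(100, 200, "rep1", "+")], [_peak(150, 250, "rep2", "-")], 1000
        )
        assert merged == []


class TestLibraryMatching:
    def _reads_on_exon(self, n, rng, toy_genes):
        """Half the reads inside the coding gene's first exon, half in
        intergenic space, random order."""
        reads = []
        for i in range(n):
            if i % 2 == 0:
                s = int(rng.integers(1000, 1450))
            else:
                s = int(rng.integers(4500, 5900))
            reads.append(
                ReadAlignment(GenomicInterval("chr1", s, s + 50, "+"), f"r{i}")
            )
        return reads

    def test_transcriptome_count_definition(self, toy_genes):
        inside = ReadAlignment(GenomicInterval("chr1", 1100, 1150, "+"), "a")
        intronic = ReadAlignment(GenomicInterval("chr1", 1600, 1650, "+"), "b")
        assert count_transcriptome_reads([inside, intronic], toy_genes) == 1
        assert count_transcriptome_reads([], toy_genes) == 0

    def test_transcriptome_count_matches_brute_force(self, toy_genes):
        rng = np.random.default_rng(2)
        reads = _random_reads(rng, 500, 9500)
        fast = count_transcriptome_reads(reads, toy_genes)
        brute = 0
        for r in reads:
            hit = False
            for g in toy_genes:
                for e in g.exons:
                    if (
                        r.interval.strand == g.span.strand
                        and r.interval.start < e.end
                        and e.start < r.interval.end
                    ):
                        hit = True
            brute += hit
        assert fast == brute

    def test_downsampling_reaches_exact_equality(self, toy_genes):
        rng = np.random.default_rng(0)
        large = self._reads_on_exon(1000, rng, toy_genes)
        small = self._reads_on_exon(800, rng, toy_genes)
        big_ds, small_out = downsample_to_match(large, small, toy_genes, seed=1)
        assert count_transcriptome_reads(big_ds, toy_genes) == \
            count_transcriptome_reads(small, toy_genes)
        assert small_out == small

    def test_equal_sizes_returned_unchanged(self, toy_genes):
        rng = np.random.default_rng(0)
        reads = self._reads_on_exon(100, rng, toy_genes)
        a, b = downsample_to_match(reads, list(reads), toy_genes, seed=1)
        assert a == reads and b == reads

    def test_fixed_seed_is_bit_reproducible(self, toy_genes):
        rng = np.random.default_rng(0)
        large = self._reads_on_exon(1000, rng, toy_genes)
        small = self._reads_on_exon(700, rng, toy_genes)
        out1, _ = downsample_to_match(large, small, toy_genes, seed=9)
        out2, _ = downsample_to_match(large, small, toy_genes, seed=9)
        out3, _ = downsample_to_match(large, small, toy_genes, seed=10)
        assert out1 == out2
        assert out1 != out3

    def test_empty_library_rejected(self, toy_genes):
        rng = np.random.default_rng(0)
        reads = self._reads_on_exon(10, rng, toy_genes)
        with pytest.raises(ValueError, match="empty library"):
            downsample_to_match(reads, [], toy_genes)
        intergenic_only = [
            ReadAlignment(GenomicInterval("chr1", 4500, 4550, "+"), "x")
        ]
        with pytest.raises(ValueError, match="empty library"):
            downsample_to_match(reads, intergenic_only, toy_genes)


@pytest.fixture(scope="module")
def simulated():
    from nascentrip.simulate import SimulationConfig, simulate_annotation, simulate_reads

    cfg = SimulationConfig(seed=21)
    genes, truth = simulate_annotation(cfg)
    reads, _ = simulate_reads(cfg)
    return cfg, genes, truth, reads


class TestCallPeaksProperties:
    def test_identical_rip_and_control_yield_no_peaks(self, simulated):
        _, genes, _, reads = simulated
        per_rep, reproducible, _ = call_peaks(
            [reads["igg1"], reads["igg2"]], [reads["igg1"], reads["igg2"]], genes
        )
        assert all(len(p) == 0 for p in per_rep)
        assert reproducible == []

    def test_every_peak_contains_a_seed_and_seeds_lie_in_peaks(self, simulated):
        cfg, genes, _, reads = simulated
        from nascentrip.peakcall import (
            _seed_positions, _test_arrays, call_peaks_pair, match_libraries,
        )

        config = PeakCallConfig()
        rip_m, ctrl_m = match_libraries(
            reads["rip1"], reads["igg1"], genes, seed=config.seed
        )
        for strand in ("+", "-"):
            rip_t = per_base_counts(rip_m, cfg.contig_name, strand, cfg.contig_length)
            ctrl_t = per_base_counts(ctrl_m, cfg.contig_name, strand, cfg.contig_length)
            fold, k, lam = _test_arrays(rip_t, ctrl_t, config)
            seeds = _seed_positions(fold.values, k, lam, config)
            peaks = extend_and_build_peaks(seeds, fold, rip_t, ctrl_t, config, "rep1")
            covered = np.zeros(cfg.contig_length, dtype=bool)
            for p in peaks:
                covered[p.interval.start:p.interval.end] = True
                assert seeds[(seeds >= p.interval.start) & (seeds < p.interval.end)].size > 0
            assert covered[seeds].all()

    def test_tightening_thresholds_shrinks_peak_positions(self, simulated):
        """Stringent-preset peaks are contained (as position sets) in
        relaxed-preset peaks, for each replicate."""
        _, genes, _, reads = simulated
        rip_sets = [reads["rip1"], reads["rip2"]]
        ctrl_sets = [reads["igg1"], reads["igg2"]]
        loose, _, _ = call_peaks(
            rip_sets, ctrl_sets, genes, PeakCallConfig.from_preset("replicate_track")
        )
        strict, _, _ = call_peaks(
            rip_sets, ctrl_sets, genes, PeakCallConfig.from_preset("stringent")
        )
        for strict_rep, loose_rep in zip(strict, loose):
            strict_pos = {
                (p.interval.strand, i)
                for p in strict_rep
                for i in range(p.interval.start, p.interval.end)
            }
            loose_pos = {
                (p.interval.strand, i)
                for p in loose_rep
                for i in range(p.interval.start, p.interval.end)
            }
            assert strict_pos <= loose_pos

    def test_unstranded_reads_rejected_in_stranded_mode(self, toy_genes):
        reads = [ReadAlignment(GenomicInterval("chr1", 1000, 1100), "x")] * 5
        from nascentrip.peakcall import call_peaks_pair

        with pytest.raises(ValueError, match="unstranded"):
            call_peaks_pair(reads, reads, toy_genes, PeakCallConfig(), "r")


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"w_half": -1},
            {"f_seed": 1.5, "f_ext": 2.0},
            {"f_ext": 0.5, "f_seed": 2.0},
            {"p_max": 0.0},
            {"p_max": 1.0},
            {"d_merge": -5},
            {"lambda_min": 0.0},
            {"strand_mode": "bogus"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PeakCallConfig(**kwargs)

    def test_presets(self):
        strict = PeakCallConfig.from_preset("stringent")
        loose = PeakCallConfig.from_preset("replicate_track")
        assert (strict.f_seed, strict.p_max) == (2.0, 1e-5)
        assert (loose.f_seed, loose.p_max) == (1.7, 1e-3)
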