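"""PWM p-values, repeat scanning/filtering/merging, adjacency geometry, AUC."""

import itertools

import numpy as np
import pytest

from pairdimer.core_seq import GenomicInterval, PeakSet, SignalTrack, reverse_complement
from pairdimer.repeats_adjacency import (
    DEGENERATE_RUNS,
    PositionWeightMatrix,
    RepeatMatch,
    RepeatRegion,
    default_tng_pwm,
    define_signal_free_background,
    filter_degenerate,
    merge_hh_sites,
    merge_regions,
    nearest_repeat,
    pwm_pvalue_table,
    scan_repeats,
    stratified_auc_compare,
    window_auc,
)


def _pwm(rows, background=None):
    return PositionWeightMatrix(np.array(rows, dtype=float), background=background)


class TestPwmPvalues:
    def test_width1_uniform(self):
        pwm = _pwm([[0.7, 0.1, 0.1, 0.1]])
        table = pwm_pvalue_table(pwm)
        # max-scoring base is A; its tail mass is the background mass of A
        assert table.pvalue("A") == pytest.approx(0.25)
        assert table.pvalue("C") == pytest.approx(1.0)

    @pytest.mark.parametrize("width", [2, 4, 6])
    def test_exhaustive_oracle(self, width):
        """DP tail probabilities equal brute force over all 4^width k-mers."""
        rng = np.random.default_rng(width)
        probs = rng.dirichlet(np.ones(4), size=width)
        bg = rng.dirichlet(np.ones(4) * 10)
        pwm = _pwm(probs, background=bg)
        table = pwm_pvalue_table(pwm, granularity=2000)
        kmers = ["".join(k) for k in itertools.product("ACGT", repeat=width)]
        int_scores = {k: table.int_score(k) for k in kmers}
        bg_prob = {
            k: float(np.prod([bg["ACGT".index(c)] for c in k])) for k in kmers
        }
        for probe in rng.choice(kmers, size=min(30, len(kmers)), replace=False):
            t = int_scores[probe]
            brute = sum(p for k, p in bg_prob.items() if int_scores[k] >= t)
            assert table.pvalue(probe) == pytest.approx(brute, abs=1e-12)

    def test_monotone_in_score(self):
        pwm = default_tng_pwm()
        table = pwm_pvalue_table(pwm)
        assert np.all(np.diff(table.pvalues) <= 1e-15)

    def test_granularity_floor(self):
        with pytest.raises(ValueError):
            pwm_pvalue_table(default_tng_pwm(), granularity=10)


class TestScanRepeats:
    def test_tng_tract_detected_and_strand_mirrored(self, tng_table):
        pwm, table = tng_table
        tract = "TTTG" * 10
        pad = "ACAGCGATCA" * 3
        seq = pad + tract + pad
        fwd = scan_repeats({"c": seq}, pwm, 8e-5, table=table)
        assert any(m.interval.strand == "+" for m in fwd)
        mirrored = scan_repeats({"c": reverse_complement(seq)}, pwm, 8e-5, table=table)
        L = len(seq)
        fwd_set = {(m.interval.start, m.interval.end, m.interval.strand) for m in fwd}
        mir_set = {
            (L - m.interval.end, L - m.interval.start, "+" if m.interval.strand == "-" else "-")
            for m in mirrored
        }
        assert fwd_set == mir_set

    def test_all_a_sequence_no_matches_after_filter(self, tng_table):
        """Poly-A reads as poly-T on the minus strand, which a TnG-type PWM
        scores highly; the homopolymer degenerate filter removes it, so the
        filtered pipeline reports nothing."""
        pwm, table = tng_table
        genome = {"c": "A" * 300}
        matches = scan_repeats(genome, pwm, 8e-5, table=table)
        assert all(m.interval.strand == "-" for m in matches)
        assert filter_degenerate(matches, genome) == []

    def test_threshold_one_reports_every_window(self, tng_table):
        pwm, table = tng_table
        seq = "ACGTACGTACGTACGTACGT"
        matches = scan_repeats({"c": seq}, pwm, 1.0, table=table)
        n_windows = len(seq) - pwm.width + 1
        assert len(matches) == 2 * n_windows

    def test_short_sequence_no_matches(self, tng_table):
        pwm, table = tng_table
        assert scan_repeats({"c": "TTTG"}, pwm, 1.0, table=table) == []


class TestFilterDegenerate:
    def _match(self, seq, genome, start=0):
        genome["c"] = seq
        return RepeatMatch(GenomicInterval("c", start, start + len(seq), "+"), 10.0, 1e-6)

    def test_tg_dinucleotide_run_removed(self):
        genome = {}
        m = self._match("TG" * 6, genome)
        assert filter_degenerate([m], genome) == []

    def test_ttg_tetramer_retained(self):
        genome = {}
        m = self._match("TTTG" * 4, genome)
        assert filter_degenerate([m], genome) == [m]

    def test_homopolymer_removed(self):
        genome = {}
        m = self._match("T" * 12 + "GGC", genome)
        assert filter_degenerate([m], genome) == []

    def test_idempotent(self):
        genome = {"c": "TTTG" * 10 + "TG" * 6}
        matches = [
            RepeatMatch(GenomicInterval("c", 0, 12, "+"), 5.0, 1e-5),
            RepeatMatch(GenomicInterval("c", 40, 52, "+"), 5.0, 1e-5),
        ]
        once = filter_degenerate(matches, genome)
        assert filter_degenerate(once, genome) == once

    def test_all_ten_run_types_listed(self):
        assert len(DEGENERATE_RUNS) == 10
        assert all(len(r) == 12 for r in DEGENERATE_RUNS)


class TestMergeRegions:
    def _m(self, start, end, strand="+", score=1.0):
        return RepeatMatch(GenomicInterval("c", start, end, strand), score, 1e-5)

    def test_overlapping_merged(self):
        regions = merge_regions([self._m(0, 12), self._m(8, 20)])
        assert len(regions) == 1
        assert (regions[0].interval.start, regions[0].interval.end) == (0, 20)
        assert regions[0].length_bp == 20 and regions[0].n_matches == 2

    def test_disjoint_untouched(self):
        regions = merge_regions([self._m(0, 12), self._m(20, 32)])
        assert len(regions) == 2

    def test_abutting_not_merged(self):
        regions = merge_regions([self._m(0, 12), self._m(12, 24)])
        assert len(regions) == 2

    def test_strand_of_best_scoring_match(self):
        regions = merge_regions([self._m(0, 12, "+", 1.0), self._m(5, 17, "-", 9.0)])
        assert regions[0].strand == "-"

    def test_idempotent_on_own_output(self):
        regions = merge_regions([self._m(0, 12), self._m(8, 20), self._m(40, 52)])
        rematched = [
            RepeatMatch(r.interval, r.best_score, r.best_p_value) for r in regions
        ]
        again = merge_regions(rematched)
        assert [(r.interval.start, r.interval.end) for r in again] == [
            (r.interval.start, r.interval.end) for r in regions
        ]

    def test_planted_tracts_recovered_exactly(self, tng_table):
        """One region per planted tract when scanning tract neighbourhoods
        (as in peak-restricted scans)."""
        pwm, table = tng_table
        rng = np.random.default_rng(19)
        k = 30
        loci = {}
        strands = {}
        for i in range(k):
            length = int(rng.integers(14, 45))
            tng = ("TTTG" * 20)[:length]
            tract = tng if i % 2 == 0 else reverse_complement(tng)
            pad5 = "".join(rng.choice(list("ACGT"), 12))
            pad3 = "".join(rng.choice(list("ACGT"), 12))
            loci[f"locus{i}"] = pad5 + tract + pad3
            strands[f"locus{i}"] = "+" if i % 2 == 0 else "-"
        matches = filter_degenerate(scan_repeats(loci, pwm, 8e-5, table=table), loci)
        regions = merge_regions(matches)
        assert len(regions) == k
        per_locus = {r.interval.chrom: r for r in regions}
        assert set(per_locus) == set(loci)
        for name, region in per_locus.items():
            assert region.strand == strands[name]


class TestMergeHHSites:
    def test_overlapping_sites_merged(self):
        ivs = [GenomicInterval("c", 0, 18, "+"), GenomicInterval("c", 10, 28, "+")]
        merged = merge_hh_sites(ivs)
        assert len(merged) == 1 and merged[0].end == 28

    def test_disjoint_kept(self):
        ivs = [GenomicInterval("c", 0, 18, "+"), GenomicInterval("c", 30, 48, "+")]
        assert len(merge_hh_sites(ivs)) == 2


class TestAdjacency:
    def _region(self, start, end, strand):
        return RepeatRegion(
            GenomicInterval("c", start, end, strand), strand, end - start, 1, 1.0, 1e-5
        )

    def test_upstream_plus_repeat_is_aligned(self):
        hh = GenomicInterval("c", 200, 218, "+")
        rec = nearest_repeat(hh, [self._region(100, 150, "+")])
        assert rec.distance == -50 and rec.alignment == "aligned"

    def test_downstream_minus_repeat_is_aligned(self):
        hh = GenomicInterval("c", 200, 218, "+")
        rec = nearest_repeat(hh, [self._region(300, 340, "-")])
        assert rec.distance == 82 and rec.alignment == "aligned"

    def test_downstream_plus_repeat_is_divergent(self):
        hh = GenomicInterval("c", 200, 218, "+")
        rec = nearest_repeat(hh, [self._region(300, 340, "+")])
        assert rec.distance == 82 and rec.alignment == "divergent"

    def test_abutting_distance_zero(self):
        hh = GenomicInterval("c", 100, 118, "+")
        rec = nearest_repeat(hh, [self._region(118, 150, "-")])
        assert rec.distance == 0 and rec.alignment == "aligned"

    def test_overlap_distance_zero_midpoint_rule(self):
        hh = GenomicInterval("c", 100, 118, "+")
        # repeat mostly downstream of the site midpoint, minus strand -> aligned
        rec = nearest_repeat(hh, [self._region(110, 150, "-")])
        assert rec.distance == 0 and rec.alignment == "aligned"
        rec = nearest_repeat(hh, [self._region(110, 150, "+")])
        assert rec.alignment == "divergent"

    def test_nearest_by_absolute_distance(self):
        hh = GenomicInterval("c", 200, 218, "+")
        far = self._region(500, 540, "+")
        near = self._region(240, 260, "+")
        rec = nearest_repeat(hh, [far, near])
        assert rec.nearest is near and rec.distance == 22

    def test_tie_prefers_downstream(self):
        hh = GenomicInterval("c", 200, 218, "+")
        up = self._region(150, 170, "+")  # distance -30
        down = self._region(248, 268, "+")  # distance +30
        rec = nearest_repeat(hh, [up, down])
        assert rec.distance == 30

    def test_no_repeat_on_chromosome(self):
        hh = GenomicInterval("c", 200, 218, "+")
        assert nearest_repeat(hh, [
            RepeatRegion(GenomicInterval("other", 0, 20, "+"), "+", 20, 1, 1.0, 1e-5)
        ]) is None

    def test_reflection_flips_signs_and_alignment_rule(self):
        """Negating coordinates mirrors distances and swaps the aligned clauses."""
        L = 1000
        hh = GenomicInterval("c", 200, 218, "+")
        region = self._region(300, 340, "+")
        rec = nearest_repeat(hh, [region])
        hh_r = GenomicInterval("c", L - 218, L - 200, "+")
        region_r = self._region(L - 340, L - 300, "-")  # strand flips on reflection
        rec_r = nearest_repeat(hh_r, [region_r])
        assert rec_r.distance == -rec.distance
        assert rec_r.alignment == rec.alignment


class TestWindowAuc:
    def test_constant_coverage(self):
        track = SignalTrack({"c": [(0, 1000, 1.0)]})
        assert window_auc(track, "c", 500, 100) == pytest.approx(200.0)

    def test_zero_coverage(self):
        track = SignalTrack({"c": [(0, 1000, 0.0)]})
        assert window_auc(track, "c", 500, 100) == 0.0

    def test_two_half_windows(self):
        track = SignalTrack({"c": [(0, 500, 1.0), (500, 1000, 3.0)]})
        assert window_auc(track, "c", 500, 100) == pytest.approx(400.0)

    def test_truncated_window_warns(self):
        track = SignalTrack({"c": [(0, 1000, 1.0)]})
        with pytest.warns(UserWarning, match="truncated"):
            assert window_auc(track, "c", 20, 100) == pytest.approx(120.0)


class TestSignalFreeBackground:
    def test_distance_rule(self):
        track = SignalTrack({"c": [(0, 100_000, 0.0)]})
        fg = PeakSet([GenomicInterval("c", 0, 1000)])
        ocrs = PeakSet([GenomicInterval("c", 6000, 7000), GenomicInterval("c", 50_000, 51_000)])
        free = define_signal_free_background(ocrs, fg, track, fg_min_auc=1.0)
        assert [iv.start for iv in free] == [50_000]

    def test_signal_rule(self):
        track = SignalTrack({"c": [(0, 200_000, 0.0), (200_000, 201_000, 5.0)]})
        fg = PeakSet([GenomicInterval("c", 0, 1000)])
        ocrs = PeakSet(
            [GenomicInterval("c", 200_000, 201_000), GenomicInterval("c", 100_000, 101_000)]
        )
        free = define_signal_free_background(ocrs, fg, track, fg_min_auc=10.0)
        assert [iv.start for iv in free] == [100_000]

    def test_empty_foreground_rejected(self):
        track = SignalTrack({"c": [(0, 1000, 1.0)]})
        with pytest.raises(ValueError):
            define_signal_free_background(PeakSet([]), PeakSet([]), track)

    def test_synthetic_bound_excluded_free_retained(self, default_bundle):
        b = default_bundle
        free = define_signal_free_background(b.bg_peaks, b.fg_peaks, b.track)
        free_keys = {(iv.chrom, iv.start) for iv in free}
        truth_free = {
            (b.bg_peaks[i].chrom, b.bg_peaks[i].start) for i in b.truth["ocr_free"]
        }
        truth_bound = {
            (b.bg_peaks[i].chrom, b.bg_peaks[i].start) for i in b.truth["ocr_bound"]
        }
        assert not (free_keys & truth_bound)
        assert len(free_keys & truth_free) >= 0.95 * len(truth_free)


class TestStratifiedAuc:
    def test_identical_track_equal_medians(self):
        track = SignalTrack({"c": [(0, 10_000, 2.0)]})
        regions = [
            RepeatRegion(GenomicInterval("c", s, s + L, "+"), "+", L, 1, 1.0, 1e-5)
            for s, L in [(1000, 15), (3000, 50), (5000, 18), (7000, 45)]
        ]
        hh = [GenomicInterval("c", 1015, 1033, "+"), GenomicInterval("c", 3050, 3068, "+")]
        res = stratified_auc_compare(regions, hh, track, far_min=500)
        medians = [v["median"] for v in res.values() if not v["empty"]]
        assert np.allclose(medians, medians[0])

    def test_single_member_group_median(self):
        track = SignalTrack({"c": [(0, 10_000, 4.0)]})
        regions = [RepeatRegion(GenomicInterval("c", 5000, 5018, "+"), "+", 18, 1, 1.0, 1e-5)]
        res = stratified_auc_compare(regions, [], track)
        assert res["short_far"]["n"] == 1
        assert res["short_far"]["median"] == pytest.approx(np.log2(800 + 1))

    def test_planted_boost_ordering(self, default_bundle):
        """Adjacent H-H boosts short repeats far more than long ones."""
        b = default_bundle
        res = stratified_auc_compare(
            b.truth_repeat_regions(), b.truth_hh_intervals(), b.track
        )
        assert all(not res[g]["empty"] for g in res)
        assert res["short_adjacent"]["median"] > res["short_far"]["median"]
        short_gain = res["short_adjacent"]["median"] - res["short_far"]["median"]
        long_gain = res["long_adjacent"]["median"] - res["long_far"]["median"]
        assert short_gain > long_gain
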