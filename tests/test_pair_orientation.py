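"""Pair dictionary, shifted-window scanning, baselines, and normalisation."""

import numpy as np
import pytest
from scipy import stats

from pairdimer.core_seq import LibraryDesign, reverse_complement
from pairdimer.pair_orientation import (
    DEFAULT_MOTIFS,
    DEFAULT_SHIFTS,
    ORIENTATIONS,
    MotifPair,
    baseline_table,
    build_pair_dictionary,
    count_pair_matches,
    count_pair_matches_sites,
    extract_shifted_windows,
    normalize_pair_counts,
    pair_baseline_probability,
)
from pairdimer.synthetic_data import (
    BindingModel,
    simulate_oligo_pdseq,
    windows_from_sites,
)

DESIGN = LibraryDesign.random_random()


class TestDictionary:
    def test_size_is_400(self):
        assert len(build_pair_dictionary(DEFAULT_MOTIFS)) == 10 * 10 * 4 == 400

    def test_inverted_repeat_pattern(self):
        pair = MotifPair("TGTTTNN", "TGTTTNN", "HH", "TCGA")
        assert pair.pattern == "TGTTTNNTCGANNAAACA"

    def test_orientation_formulas(self):
        a, b, gap = "TGTTKNN", "NNGCATY", "TCGA"
        assert MotifPair(a, b, "HT", gap).pattern == a + gap + b
        assert MotifPair(a, b, "TH", gap).pattern == reverse_complement(a) + gap + reverse_complement(b)
        assert MotifPair(a, b, "TT", gap).pattern == reverse_complement(a) + gap + b

    def test_strand_symmetry_identities(self):
        """rc(HT(a,b)) == TH(b,a); rc(HH(a,b)) == HH(b,a); rc(TT(a,b)) == TT(b,a).

        Scanning the opposite strand therefore converts T-H into H-T and
        transposes the H-H and T-T matrices.
        """
        for a in DEFAULT_MOTIFS:
            for b in DEFAULT_MOTIFS:
                assert reverse_complement(MotifPair(a, b, "HT").pattern) == MotifPair(b, a, "TH").pattern
                assert reverse_complement(MotifPair(a, b, "HH").pattern) == MotifPair(b, a, "HH").pattern
                assert reverse_complement(MotifPair(a, b, "TT").pattern) == MotifPair(b, a, "TT").pattern

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_pair_dictionary(["TGTTTAC", "ACGT"])


class TestShiftedWindows:
    READ = DESIGN.nbs1 + "GATTACA" + "TCGA" + "CCGGTTA" + DESIGN.nbs2

    def test_five_windows(self):
        ws = extract_shifted_windows(self.READ, DESIGN)
        assert ws is not None and len(ws) == 5

    def test_shift_zero_is_core(self):
        ws = extract_shifted_windows(self.READ, DESIGN, shifts=(0,))
        assert ws == ["GATTACA" + "TCGA" + "CCGGTTA"]

    def test_positive_shift_pulls_flank_bases(self):
        ws = extract_shifted_windows(self.READ, DESIGN, shifts=(2,))
        expected = "TTACA" + "TCGA" + "CCGGTTA" + DESIGN.nbs2[:2]
        assert ws == [expected]

    def test_negative_shift_pulls_upstream_flank(self):
        ws = extract_shifted_windows(self.READ, DESIGN, shifts=(-2,))
        expected = DESIGN.nbs1[-2:] + "GATTACA" + "TCGA" + "CCGGT"
        assert ws == [expected]

    def test_unlocatable_structure(self):
        assert extract_shifted_windows("ACGT" * 20, DESIGN) is None

    def test_windows_from_sites_agrees_with_string_path(self):
        rng = np.random.default_rng(0)
        s1 = rng.integers(0, 4, (20, 7), dtype=np.uint8)
        s2 = rng.integers(0, 4, (20, 7), dtype=np.uint8)
        arr = windows_from_sites(s1, s2, DESIGN, DEFAULT_SHIFTS)
        conv = "ACGT"
        for i in range(20):
            site1 = "".join(conv[c] for c in s1[i])
            site2 = "".join(conv[c] for c in s2[i])
            read = DESIGN.nbs1 + site1 + DESIGN.gap + site2 + DESIGN.nbs2
            ws = extract_shifted_windows(read, DESIGN)
            got = [
                bytes(arr[i * 5 + k]).decode("ascii") for k in range(5)
            ]
            assert got == ws


class TestCountPairMatches:
    def test_exact_inverted_repeat_read_counts_hh(self):
        dic = build_pair_dictionary(["TGTTTAC", "NNGCATY"])
        read = DESIGN.nbs1 + "TGTTTAC" + "TCGA" + "GTAAACA" + DESIGN.nbs2
        cm = count_pair_matches([read], dic, DESIGN)
        assert cm.value("TGTTTAC", "TGTTTAC", "HH") == 1

    def test_once_per_read_even_with_multiple_shift_hits(self):
        # all-N motif matches at every shift, still counted once
        dic = build_pair_dictionary(["NNNNNNN"])
        read = DESIGN.nbs1 + "GATTACA" + "TCGA" + "CCGGTTA" + DESIGN.nbs2
        cm = count_pair_matches([read], dic, DESIGN)
        for o in ORIENTATIONS:
            assert cm.value("NNNNNNN", "NNNNNNN", o) == 1

    def test_total_counts_bounded_by_reads(self):
        rng = np.random.default_rng(1)
        reads = [
            DESIGN.nbs1
            + "".join(rng.choice(list("ACGT"), 7))
            + "TCGA"
            + "".join(rng.choice(list("ACGT"), 7))
            + DESIGN.nbs2
            for _ in range(200)
        ]
        dic = build_pair_dictionary(DEFAULT_MOTIFS)
        cm = count_pair_matches(reads, dic, DESIGN)
        assert cm.counts.max() <= 200


class TestBaseline:
    def test_all_n_pattern_is_certain(self):
        pair = MotifPair("NNNNNNN", "NNNNNNN", "HT", "NNNN")
        assert pair_baseline_probability(pair, DESIGN, shifts=(0,)) == pytest.approx(1.0)

    def test_fully_specified_site1_single_shift(self):
        # site 1 fixed to a concrete 7-mer, gap matches the design, site 2 all-N
        pair = MotifPair("TGTTTAC", "NNNNNNN", "HT", "TCGA")
        p = pair_baseline_probability(pair, DESIGN, shifts=(0,))
        assert p == pytest.approx((1 / 4) ** 7)

    def test_monotone_in_degeneracy(self):
        """Adding an N never decreases the baseline."""
        base = "TGTTTAC"
        pair0 = MotifPair(base, "TGTTTAC", "HH")
        p0 = pair_baseline_probability(pair0, DESIGN)
        for i in range(7):
            relaxed = base[:i] + "N" + base[i + 1 :]
            p1 = pair_baseline_probability(MotifPair(relaxed, "TGTTTAC", "HH"), DESIGN)
            assert p1 >= p0

    def test_gap_mismatch_gives_zero_at_shift0(self):
        pair = MotifPair("NNNNNNN", "NNNNNNN", "HT", "AAAA")
        assert pair_baseline_probability(pair, DESIGN, shifts=(0,)) == 0.0

    @pytest.mark.parametrize(
        "pair",
        [
            MotifPair("TGTNNNN", "TGTNNNN", "HH"),
            MotifPair("NNGCATY", "TGTTKNN", "HT"),
            MotifPair("NNNNNNN", "TGTTTNN", "TT"),
        ],
    )
    def test_monte_carlo_agreement(self, pair):
        """Analytic baseline within 3 Monte-Carlo SE of an empirical estimate."""
        from pairdimer.pair_orientation import _encode_patterns, _encode_texts

        n = 10**6
        rng = np.random.default_rng(17)
        s1 = rng.integers(0, 4, (n, 7), dtype=np.uint8)
        s2 = rng.integers(0, 4, (n, 7), dtype=np.uint8)
        w = windows_from_sites(s1, s2, DESIGN, DEFAULT_SHIFTS)
        wl, wh = _encode_texts(w)
        pl, ph = _encode_patterns([pair.pattern])
        hit = (((wl & ~pl[0]) | (wh & ~ph[0])) == 0).reshape(n, 5).any(axis=1)
        emp = hit.mean()
        se = max(np.sqrt(emp * (1 - emp) / n), 1e-9)
        analytic = pair_baseline_probability(pair, DESIGN)
        assert abs(analytic - emp) <= 3 * se


class TestNormalize:
    def _uniform_matrix(self, motifs, value, n_reads=100):
        cm = count_pair_matches([], build_pair_dictionary(motifs), DESIGN)
        cm.counts = np.full_like(cm.counts, value, dtype=float)
        return cm

    def test_uniform_counts_uniform_baselines(self):
        motifs = ["NNNNNNN"]
        cm = self._uniform_matrix(motifs, 10.0)
        baselines = {(a, b, o): 0.5 for a in motifs for b in motifs for o in ORIENTATIONS}
        norm = normalize_pair_counts(cm, baselines)
        assert np.allclose(norm.counts, 20.0)

    def test_zero_baseline_flagged_as_zero(self):
        motifs = ["NNNNNNN"]
        cm = self._uniform_matrix(motifs, 10.0)
        baselines = {(a, b, o): 0.0 for a in motifs for b in motifs for o in ORIENTATIONS}
        norm = normalize_pair_counts(cm, baselines)
        assert np.all(norm.counts == 0.0)

    def test_joint_scaling_common_max_100(self):
        motifs = ["NNNNNNN"]
        cm1 = self._uniform_matrix(motifs, 10.0)
        cm2 = self._uniform_matrix(motifs, 40.0)
        baselines = {(a, b, o): 1.0 for a in motifs for b in motifs for o in ORIENTATIONS}
        n1, n2 = normalize_pair_counts(cm1, baselines, joint_scale_with=cm2)
        assert n2.counts.max() == pytest.approx(100.0)
        assert n1.counts.max() == pytest.approx(25.0)
        assert max(n1.counts.max(), n2.counts.max()) == pytest.approx(100.0)


class TestOrientationRecovery:
    """Planted-model recovery of the head-to-head orientational bias."""

    def test_hh_bonus_model_dominates_hh(self):
        model = BindingModel.dimer_like(shifts=DEFAULT_SHIFTS)
        sim = simulate_oligo_pdseq(DESIGN, model, n_input=1000, n_pd=200_000, seed=5)
        dic = build_pair_dictionary(DEFAULT_MOTIFS)
        cm = count_pair_matches_sites(sim.pd_site1, sim.pd_site2, dic, DESIGN)
        totals = cm.orientation_totals()
        assert all(totals["HH"] > totals[o] for o in ("HT", "TH", "TT"))
        # the planted pair is the top normalised cell
        norm = normalize_pair_counts(cm, baseline_table(dic, DESIGN))
        ia, ib, k = np.unravel_index(np.argmax(norm.counts), norm.counts.shape)
        assert (norm.motifs[ia], norm.motifs[ib], ORIENTATIONS[k]) == ("TGTTTNN", "TGTTTNN", "HH")

    def test_monomer_model_shows_no_orientation_bias(self):
        """A single-half-site binder is orientation-symmetric (uniform totals)."""
        model = BindingModel.monomer_like(30.0)
        sim = simulate_oligo_pdseq(DESIGN, model, n_input=1000, n_pd=200_000, seed=6)
        dic = build_pair_dictionary(DEFAULT_MOTIFS)
        cm = count_pair_matches_sites(sim.pd_site1, sim.pd_site2, dic, DESIGN)
        totals = np.array(list(cm.orientation_totals().values()))
        assert stats.chisquare(totals).pvalue > 0.01
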