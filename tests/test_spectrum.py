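"""Spectrum classification, chi-square statistics, CpG islands, annotation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from triodnm.io import Transcript
from triodnm.simulate import SimConfig, generate_annotation, _iid_sequence, \
    _island_sequence
from triodnm.spectrum import (
    COMPLEMENT,
    CgiParams,
    FeatureIndex,
    MutationClassCounts,
    annotate_feature,
    brute_force_cpg_islands,
    build_spectrum,
    chi_square_gof,
    classify_cgi,
    classify_mutation,
    detect_cpg_islands,
    feature_randomness_test,
    repeats_to_trees,
    sw_bias_test,
    ts_tv_ratio,
)


class TestClassification:
    @pytest.mark.parametrize("ref,alt,ctx,expected", [
        ("C", "T", "ACG", "C>T_CpG"),   # CpG dinucleotide
        ("G", "A", "CGT", "C>T_CpG"),   # reverse-strand CpG
        ("A", "G", "TAT", "A>G"),
        ("T", "C", "ATA", "A>G"),       # collapse of T>C
        ("C", "T", "ACA", "C>T"),
        ("C", "A", "TCT", "C>A"),
        ("G", "T", "AGA", "C>A"),       # collapse of G>T
        ("A", "T", "CAC", "A>T"),
    ])
    def test_examples(self, ref, alt, ctx, expected):
        cls, ambiguous = classify_mutation(ref, alt, ctx)
        assert cls == expected and not ambiguous

    def test_ambiguous_context_flagged(self):
        cls, ambiguous = classify_mutation("C", "T", "ACN")
        assert cls == "C>T" and ambiguous

    @settings(max_examples=200, derandomize=True)
    @given(
        ref=st.sampled_from("ACGT"),
        alt=st.sampled_from("ACGT"),
        left=st.sampled_from("ACGT"),
        right=st.sampled_from("ACGT"),
    )
    def test_strand_involution(self, ref, alt, left, right):
        """Complementing ref/alt/context never changes the class."""
        if ref == alt:
            return
        ctx = f"{left}{ref}{right}"
        rc = "".join(COMPLEMENT[b] for b in reversed(ctx))
        a, _ = classify_mutation(ref, alt, ctx)
        b, _ = classify_mutation(COMPLEMENT[ref], COMPLEMENT[alt], rc)
        assert a == b

    def test_spectrum_counts_conserved(self):
        muts = [("C", "T", "ACG"), ("A", "G", "AAA"), ("G", "C", "TGT"),
                ("T", "A", "CTC")]
        counts = build_spectrum(muts)
        assert counts.total == len(muts)
        assert counts.ts + counts.tv == counts.total


class TestTsTv:
    def test_headline_ratio(self):
        counts = MutationClassCounts()
        counts.counts["A>G"] = 30
        counts.counts["C>T"] = 23
        counts.counts["C>T_CpG"] = 10  # ts = 63
        counts.counts["C>A"] = 30
        counts.counts["A>T"] = 22  # tv = 52
        assert ts_tv_ratio(counts) == pytest.approx(1.21, abs=0.005)

    def test_balanced_and_simple_ratios(self):
        counts = MutationClassCounts()
        counts.counts["A>G"] = 2
        counts.counts["C>G"] = 1
        assert ts_tv_ratio(counts) == pytest.approx(2.0)
        counts.counts["C>G"] = 2
        assert ts_tv_ratio(counts) == pytest.approx(1.0)

    def test_no_transversions_undefined(self):
        counts = MutationClassCounts()
        counts.counts["A>G"] = 5
        with pytest.raises(ZeroDivisionError):
            ts_tv_ratio(counts)


class TestChiSquare:
    @pytest.mark.parametrize("observed,expected_stat", [
        ((26, 29), 0.16),
        ((108, 125), 1.24),
        ((10, 10), 0.0),
    ])
    def test_one_to_one_examples(self, observed, expected_stat):
        res = chi_square_gof(observed, [0.5, 0.5])
        assert res.statistic == pytest.approx(expected_stat, abs=0.005)
        assert res.df == 1

    def test_matches_closed_form_to_1e12(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(2, 6)
            obs = rng.integers(1, 200, size=k).astype(float)
            props = rng.dirichlet(np.ones(k))
            res = chi_square_gof(obs, props)
            exp = props * obs.sum()
            manual = float(((obs - exp) ** 2 / exp).sum())
            assert abs(res.statistic - manual) < 1e-12
            scipy_stat, scipy_p = stats.chisquare(obs, exp)
            assert abs(res.statistic - scipy_stat) < 1e-9
            assert abs(res.p_value - scipy_p) < 1e-9

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            chi_square_gof([5, 5], [1.0, 0.0])


class TestSwBias:
    def test_null_case(self):
        muts = [("C", "A")] * 50 + [("A", "C")] * 50
        res = sw_bias_test(muts, 0.5)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        muts = [("C", "T")] * 26 + [("A", "G")] * 29
        res = sw_bias_test(muts, 0.5)
        assert res.statistic == pytest.approx(0.1636, abs=2e-4)

    def test_within_class_changes_excluded(self):
        muts = [("C", "G")] * 30 + [("A", "T")] * 30 + [("C", "A")] * 10 \
            + [("A", "C")] * 10
        res = sw_bias_test(muts, 0.5)
        assert sum(res.observed) == 20

    def test_type_i_error_near_nominal(self):
        """Under a symmetric model the 5% test rejects about 5% of the time."""
        rng = np.random.default_rng(5)
        gc = 0.4
        n = 200
        rejections = 0
        reps = 1000
        for _ in range(reps):
            sw = rng.binomial(n, gc)
            res = chi_square_gof([sw, n - sw], [gc, 1 - gc])
            rejections += res.p_value < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / reps) + 0.01


def _seq_str(arr):
    return "".join("ACGT"[b] for b in arr)


class TestCpgIslands:
    def test_cg_repeat_is_one_island(self):
        seq = "CG" * 150
        islands = detect_cpg_islands(seq)
        assert len(islands) == 1
        isl = islands[0]
        assert isl.start == 0 and isl.end == 300
        assert isl.gc_fraction == 1.0 and isl.obs_exp_cpg > 0.6

    def test_poly_a_has_no_islands(self):
        assert detect_cpg_islands("A" * 1000) == []

    def test_too_short_sequence(self):
        assert detect_cpg_islands("CG" * 50) == []

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_brute_force_oracle_on_2kb(self, seed):
        """Detector equals the quadratic all-substring oracle."""
        rng = np.random.default_rng(seed)
        bg = _iid_sequence(2000, 0.35, rng)
        ins = _island_sequence(400, 0.62, rng)
        start = int(rng.integers(200, 1400))
        arr = bg.copy()
        arr[start:start + 400] = ins
        seq = _seq_str(arr)
        fast = [(i.start, i.end) for i in detect_cpg_islands(seq)]
        oracle = [(i.start, i.end) for i in brute_force_cpg_islands(seq)]
        assert fast == oracle

    def test_matches_oracle_without_any_island(self):
        rng = np.random.default_rng(9)
        seq = _seq_str(_iid_sequence(1500, 0.45, rng))
        fast = [(i.start, i.end) for i in detect_cpg_islands(seq)]
        oracle = [(i.start, i.end) for i in brute_force_cpg_islands(seq)]
        assert fast == oracle

    def test_single_insert_detected_once_and_covers_insert(self):
        rng = np.random.default_rng(11)
        bg = _iid_sequence(1000, 0.3, rng)
        ins = _island_sequence(400, 0.6, rng)
        arr = bg.copy()
        arr[300:700] = ins
        islands = detect_cpg_islands(_seq_str(arr))
        assert len(islands) == 1
        isl = islands[0]
        assert isl.start <= 320 and isl.end >= 680

    def test_custom_thresholds_respected(self):
        # 60 bp CpG block: even diluted, GC >= 0.5 holds only out to 120 bp,
        # short of the default 200 bp minimum
        seq = "CG" * 30 + "A" * 500
        assert detect_cpg_islands(seq) == []
        loose = CgiParams(min_length=100)
        islands = detect_cpg_islands(seq, params=loose)
        assert len(islands) == 1 and islands[0].end <= 120


def _single_transcript(strand="+"):
    # exon1 100-200 (CDS 130-200), intron, exon2 300-400 (CDS 300-370)
    return Transcript(
        tid="tx1", chrom="chr1", start=100, end=400, strand=strand,
        exons=[(100, 200), (300, 400)],
        cds=[(130, 200, 0), (300, 370, (3 - 70 % 3) % 3)]
        if strand == "+" else [(130, 200, (3 - 70 % 3) % 3), (300, 370, 0)],
    )


class TestCgiClassification:
    def _island(self, start, end):
        from triodnm.spectrum import CpgIsland
        return CpgIsland(chrom="chr1", start=start, end=end,
                         gc_fraction=0.6, obs_exp_cpg=0.8)

    def test_priority_and_classes(self):
        index = FeatureIndex([_single_transcript()], tss_tts_window=50)
        assert classify_cgi(self._island(90, 120), index) == "TSS"
        assert classify_cgi(self._island(380, 420), index) == "TTS"
        assert classify_cgi(self._island(160, 190), index) == "exonic"
        assert classify_cgi(self._island(220, 280), index) == "intronic"
        assert classify_cgi(self._island(600, 900), index) == "intergenic"

    def test_tss_beats_exonic(self):
        index = FeatureIndex([_single_transcript()], tss_tts_window=50)
        # island spanning both the TSS window and exon 1
        assert classify_cgi(self._island(95, 180), index) == "TSS"


class TestFeatureAnnotation:
    @pytest.fixture()
    def setup(self):
        cfg = SimConfig(n_families=1, n_offspring_per_family=1,
                        callable_length=60_000, n_chromosomes=1, seed=2)
        from triodnm.simulate import generate_reference, reference_to_str
        ref = reference_to_str(generate_reference(cfg))
        tx = generate_annotation(cfg, mean_gene_length=4000, gene_spacing=6000)
        return ref, tx, FeatureIndex(tx)

    def test_synonymous_vs_missense_on_constructed_gene(self):
        """GCT->GCC is silent, GCT->GTT is Ala->Val."""
        seq = "A" * 100 + "ATGGCTTAA" + "A" * 100
        ref = {"chr1": seq}
        tx = Transcript(tid="t", chrom="chr1", start=100, end=109, strand="+",
                        exons=[(100, 109)], cds=[(100, 109, 0)])
        index = FeatureIndex([tx])
        # codon 2 is GCT at 103-106 (0-based); third base at pos0 105
        silent = annotate_feature("chr1", 106, "C", index, ref)
        assert silent.feature == "exonic_synonymous"
        missense = annotate_feature("chr1", 105, "T", index, ref)
        assert missense.feature == "exonic_missense"

    def test_reverse_strand_effect(self):
        # reverse-strand gene: genomic TTAAGCCAT reverse-complements to ATGGCTTAA
        seq = "A" * 100 + "TTAAGCCAT" + "A" * 100
        ref = {"chr1": seq}
        tx = Transcript(tid="t", chrom="chr1", start=100, end=109, strand="-",
                        exons=[(100, 109)], cds=[(100, 109, 0)])
        index = FeatureIndex([tx])
        # genomic pos0 103 is the G pairing with codon2 third base (C on -)
        res = annotate_feature("chr1", 104, "G", index, ref)
        assert res.feature == "exonic_synonymous"

    def test_utr_intron_intergenic_and_repeats(self, setup):
        ref, tx, index = setup
        t = tx[0]
        utr_pos = t.exons[0][0] + 1  # first exon before CDS start
        res = annotate_feature(t.chrom, utr_pos + 1, "A", index, ref)
        assert res.feature == "exonic_UTR"
        intron_pos = t.exons[0][1] + 10
        res = annotate_feature(t.chrom, intron_pos + 1, "A", index, ref)
        assert res.feature == "intronic"
        repeats = repeats_to_trees([("chr1", 0, 50)])
        res = annotate_feature("chr1", 10, "A", index, ref, repeats)
        assert res.feature in ("intergenic",) and res.repetitive

    def test_planted_coding_mutation_translates_consistently(self, setup):
        """Every CDS position annotates to a coding effect, never intergenic."""
        ref, tx, index = setup
        for t in tx[:3]:
            s, e, _ = t.cds[0]
            for pos0 in range(s + 3, s + 9):
                base = ref[t.chrom][pos0]
                alt = "A" if base != "A" else "G"
                res = annotate_feature(t.chrom, pos0 + 1, alt, index, ref)
                assert res.feature.startswith("exonic_")


class TestFeatureRandomness:
    def test_exact_proportionality_gives_zero(self):
        res = feature_randomness_test([20, 30, 50], [2e6, 3e6, 5e6])
        assert res.statistic == pytest.approx(0.0)

    def test_equal_thirds_hand_value(self):
        res = feature_randomness_test([21, 53, 41], [1e6, 1e6, 1e6])
        assert res.statistic == pytest.approx(13.6, abs=0.05)
        assert res.df == 2

    def test_null_p_values_roughly_uniform(self):
        """Counts drawn from the expected proportions give uniform p (KS)."""
        rng = np.random.default_rng(8)
        props = np.array([0.2, 0.3, 0.5])
        ps = []
        for _ in range(500):
            obs = rng.multinomial(300, props)
            ps.append(feature_randomness_test(obs, props * 1e6).p_value)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.001
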