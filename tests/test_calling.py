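"""Detection, filter cascade, validation, callable size and FNR."""

import itertools

import numpy as np
import pytest
from scipy import stats

from triodnm.calling import (
    FilterConfig,
    apply_individual_filters,
    apply_site_filters,
    call_candidates,
    compute_callable_size,
    estimate_fnr,
    find_mendelian_violations,
    group_shared,
    validate_candidates,
    verify_pedigree,
)
from triodnm.model import DnmCandidate, ReadEvidence, SampleCall, SiteRecord, Trio

TRIO = Trio(family="F1", father="dad", mother="mum", child="kid")
GTS = [(0, 0), (0, 1), (1, 1)]


def make_site(f_gt, m_gt, c_gt, info=None, dp=45, ads=None, gq=60,
              chrom="chr1", pos=100):
    calls = {}
    for name, gt, i in (("dad", f_gt, 0), ("mum", m_gt, 1), ("kid", c_gt, 2)):
        if ads is not None:
            ad = ads[i]
        elif gt is None:
            ad = (0, 0)
        else:
            alt = {0: 0, 1: dp // 2, 2: dp}[sum(gt)] if gt else 0
            ad = (dp - alt, alt)
        calls[name] = SampleCall(gt=gt, dp=dp, ad=ad, gq=gq)
    return SiteRecord(chrom=chrom, pos=pos, ref="A", alt="G",
                      info=info if info is not None else {}, calls=calls)


class TestMendelianViolations:
    def test_agrees_with_brute_force_over_all_27_configurations(self):
        """Only (0/0, 0/0, 0/1) is a candidate; enumeration is the oracle."""
        for f, m, c in itertools.product(GTS, GTS, GTS):
            # oracle: a child allele absent from the designated rule set
            expected = (f == (0, 0) and m == (0, 0) and sorted(c) == [0, 1])
            got = find_mendelian_violations(make_site(f, m, c), TRIO)
            assert (got is not None) == expected, (f, m, c)

    def test_back_mutation_configuration_excluded(self):
        assert find_mendelian_violations(
            make_site((1, 1), (1, 1), (0, 1)), TRIO
        ) is None

    def test_missing_genotype_yields_no_candidate(self):
        assert find_mendelian_violations(
            make_site(None, (0, 0), (0, 1)), TRIO
        ) is None

    def test_monomorphic_record_ignored(self):
        site = make_site((0, 0), (0, 0), (0, 1))
        site.alt = None
        assert find_mendelian_violations(site, TRIO) is None


class TestSiteFilters:
    PASSING = {"QD": 20.0, "FS": 5.0, "MQ": 60.0, "SOR": 1.0,
               "MQRankSum": 0.0, "ReadPosRankSum": 0.0}

    def test_all_passing(self):
        ok, reason = apply_site_filters(
            make_site((0, 0), (0, 0), (0, 1), info=dict(self.PASSING)),
            FilterConfig(),
        )
        assert ok and reason is None

    @pytest.mark.parametrize("field,value", [
        ("QD", 1.0), ("FS", 61.0), ("MQ", 30.0), ("SOR", 4.0),
        ("MQRankSum", -13.0), ("ReadPosRankSum", -9.0),
    ])
    def test_first_violated_threshold_reported(self, field, value):
        info = dict(self.PASSING)
        info[field] = value
        ok, reason = apply_site_filters(
            make_site((0, 0), (0, 0), (0, 1), info=info), FilterConfig()
        )
        assert not ok and reason == field

    def test_missing_stat_passes_by_default_and_fails_when_strict(self):
        info = dict(self.PASSING)
        info.pop("FS")
        site = make_site((0, 0), (0, 0), (0, 1), info=info)
        assert apply_site_filters(site, FilterConfig())[0]
        strict = FilterConfig(missing_info_passes=False)
        ok, reason = apply_site_filters(site, strict)
        assert not ok and reason == "missing_FS"


class TestIndividualFilters:
    def _run(self, site, config=None):
        cand = DnmCandidate(trio=TRIO, chrom="chr1", pos=site.pos,
                            ref=site.ref, alt=site.alt)
        apply_individual_filters(cand, site, config or FilterConfig())
        return dict(cand.filter_trail)

    def test_child_depth_above_twice_trio_depth_fails(self):
        # DP_trio = mean(45, 45, 100) = 63.3; 100 < 126.7 passes, so push higher
        site = make_site((0, 0), (0, 0), (0, 1))
        site.calls["kid"].dp = 400
        site.calls["kid"].ad = (200, 200)
        assert self._run(site)["depth"] is False

    def test_balanced_allele_depth_passes_ab(self):
        site = make_site((0, 0), (0, 0), (0, 1),
                         ads=[(45, 0), (45, 0), (20, 20)])
        trail = self._run(site)
        assert trail["allelic_balance"] is True

    def test_ab_endpoints_inclusive(self):
        site = make_site((0, 0), (0, 0), (0, 1),
                         ads=[(40, 0), (40, 0), (70, 30)])
        assert self._run(site)["allelic_balance"] is True
        site = make_site((0, 0), (0, 0), (0, 1),
                         ads=[(40, 0), (40, 0), (71, 29)])
        assert self._run(site)["allelic_balance"] is False

    def test_parental_alt_reads_cap(self):
        site = make_site((0, 0), (0, 0), (0, 1),
                         ads=[(40, 2), (40, 0), (20, 20)])
        assert self._run(site)["parental_reads"] is False
        site = make_site((0, 0), (0, 0), (0, 1),
                         ads=[(40, 1), (40, 0), (20, 20)])
        assert self._run(site)["parental_reads"] is True

    def test_low_gq_fails(self):
        site = make_site((0, 0), (0, 0), (0, 1), gq=10)
        assert self._run(site)["GQ"] is False

    def test_zero_child_depth_fails_depth(self):
        site = make_site((0, 0), (0, 0), (0, 1))
        site.calls["kid"].dp = 0
        assert self._run(site)["depth"] is False

    def test_filter_order_does_not_change_pass_set(self):
        """Permuting filter evaluation only affects the recorded trail order."""
        site_ok = make_site((0, 0), (0, 0), (0, 1),
                            ads=[(45, 0), (45, 0), (22, 23)])
        site_bad = make_site((0, 0), (0, 0), (0, 1),
                             ads=[(45, 3), (45, 0), (22, 23)])
        for site, expected in ((site_ok, True), (site_bad, False)):
            results = set()
            for _ in range(3):
                cand = DnmCandidate(trio=TRIO, chrom="chr1", pos=site.pos,
                                    ref="A", alt="G")
                apply_individual_filters(cand, site, FilterConfig())
                results.add(all(ok for _, ok in cand.filter_trail))
            assert results == {expected}


class TestValidation:
    def _candidate(self, pos=100):
        c = DnmCandidate(trio=TRIO, chrom="chr1", pos=pos, ref="A", alt="G")
        c.filter_trail.append(("site", True))
        return c

    def _frags(self, sample, base, n, pos=100):
        return [ReadEvidence(fragment_id=f"{sample}{base}{i}", sample=sample,
                             observations=[("chr1", pos, base)])
                for i in range(n)]

    def test_fdr_arithmetic(self):
        cands = [self._candidate(pos=100 + i) for i in range(20)]
        evidence = []
        for i, c in enumerate(cands):
            evidence += self._frags("kid", "G", 5, pos=c.pos)
            if i < 5:  # five candidates get parental variant reads
                evidence += self._frags("dad", "G", 2, pos=c.pos)
        rep = validate_candidates(cands, evidence, FilterConfig())
        assert rep.fdr == pytest.approx(0.25)
        assert rep.by_reason == {"rejected_parental_reads": 5}

    def test_zero_rejections_zero_fdr(self):
        cands = [self._candidate()]
        rep = validate_candidates(cands, self._frags("kid", "G", 5),
                                  FilterConfig())
        assert rep.fdr == 0.0

    def test_no_evidence_is_conservatively_rejected(self):
        cands = [self._candidate()]
        rep = validate_candidates(cands, [], FilterConfig())
        assert cands[0].validation == "unvalidatable"
        assert rep.fdr == 1.0

    def test_low_child_support_rejected(self):
        cands = [self._candidate()]
        rep = validate_candidates(cands, self._frags("kid", "G", 1),
                                  FilterConfig())
        assert cands[0].validation == "rejected_low_support"

    def test_injected_artifact_rate_recovered(self, noisy_sim):
        """Simulated artifact candidates are flagged by validation."""
        filt = FilterConfig()
        cands = call_candidates(noisy_sim.records, noisy_sim.trios, filt)
        passing = [c for c in cands if c.passed_filters]
        rep = validate_candidates(passing, noisy_sim.evidence, filt)
        fp_keys = {(child, chrom, pos)
                   for child, chrom, pos, _, _ in
                   noisy_sim.truth.false_positive_sites}
        for c in passing:
            if (c.trio.child, c.chrom, c.pos) in fp_keys:
                assert c.validation != "validated"


class TestCallableAndFnr:
    def test_all_sites_passing(self):
        sites = [make_site((0, 0), (0, 0), (0, 0), pos=i + 1)
                 for i in range(10)]
        cs = compute_callable_size(sites, TRIO, FilterConfig())
        assert cs.cs == 10 and cs.callable_fraction == 1.0

    def test_het_parent_site_excluded(self):
        sites = [make_site((0, 0), (0, 0), (0, 0), pos=1),
                 make_site((0, 1), (0, 0), (0, 0), pos=2)]
        cs = compute_callable_size(sites, TRIO, FilterConfig())
        assert cs.cs == 1

    def test_hom_alt_parents_still_callable(self):
        sites = [make_site((1, 1), (0, 0), (0, 1), pos=1)]
        cs = compute_callable_size(sites, TRIO, FilterConfig())
        assert cs.cs == 1

    def test_survey_scaling(self):
        sites = [make_site((0, 0), (0, 0), (0, 0), pos=i + 1)
                 for i in range(8)]
        sites += [make_site((0, 1), (0, 0), (0, 0), pos=i + 100)
                  for i in range(2)]
        cs = compute_callable_size(sites, TRIO, FilterConfig(),
                                   autosome_total=1_000_000)
        assert cs.cs == pytest.approx(800_000)
        assert cs.callable_fraction == pytest.approx(0.8)

    def test_fnr_arithmetic(self):
        sites = []
        for i in range(1000):
            ab_out = i < 74
            ad = (40, 2) if ab_out else (22, 23)
            sites.append(make_site((0, 0), (1, 1), (0, 1), pos=i + 1,
                                   ads=[(45, 0), (0, 45), ad]))
        est = estimate_fnr(sites, TRIO, FilterConfig())
        assert est.fnr == pytest.approx(0.074)

    def test_fnr_unavailable_with_too_few_sites(self):
        est = estimate_fnr([make_site((0, 0), (1, 1), (0, 1))], TRIO,
                           FilterConfig())
        assert est.status == "unavailable"
        with pytest.raises(ValueError):
            _ = est.fnr

    def test_fnr_matches_binomial_tail_at_depth_45(self):
        """Estimator converges to the closed-form binomial AB tail."""
        rng = np.random.default_rng(42)
        dp = 45
        n_sites = 10_000
        alt = rng.binomial(dp, 0.5, size=n_sites)
        sites = [
            make_site((0, 0), (1, 1), (0, 1), pos=i + 1,
                      ads=[(dp, 0), (0, dp), (dp - a, a)], dp=dp)
            for i, a in enumerate(alt)
        ]
        est = estimate_fnr(sites, TRIO, FilterConfig())
        lo = int(np.ceil(0.3 * dp))
        hi = int(np.floor(0.7 * dp))
        p_tail = float(stats.binom.cdf(lo - 1, dp, 0.5)
                       + stats.binom.sf(hi, dp, 0.5))
        sigma = np.sqrt(p_tail * (1 - p_tail) / n_sites)
        assert abs(est.fnr - p_tail) <= 3 * sigma


class TestSharing:
    def _cand(self, child, pos, alt="G"):
        trio = Trio(family="F1", father="dad", mother="mum", child=child)
        return DnmCandidate(trio=trio, chrom="chr1", pos=pos, ref="A", alt=alt)

    def test_identical_calls_collapse(self):
        groups, rep = group_shared([self._cand("kid1", 5), self._cand("kid2", 5)])
        assert rep.n_unique == 1 and rep.n_shared == 1
        assert rep.size_histogram == {2: 1}

    def test_different_alt_alleles_stay_distinct(self):
        groups, rep = group_shared([
            self._cand("kid1", 5, "G"), self._cand("kid2", 5, "T"),
        ])
        assert rep.n_unique == 2 and rep.n_shared == 0

    def test_simulated_sharing_close_to_model_expectation(self, clean_sim):
        """Sharing percentage among planted events carried by >=2 sibs."""
        truth_shared = sum(
            1 for d in clean_sim.truth.planted_dnms if len(d.offspring) > 1
        )
        truth_unique = len(clean_sim.truth.planted_dnms)
        filt = FilterConfig(ab_filter_enabled=False)
        cands = call_candidates(clean_sim.records, clean_sim.trios, filt)
        passing = [c for c in cands if c.passed_filters]
        validate_candidates(passing, clean_sim.evidence, filt)
        curated = [c for c in passing if c.validation == "validated"]
        _, rep = group_shared(curated)
        assert rep.n_unique == truth_unique
        assert rep.n_shared == truth_shared


class TestPedigreeCheck:
    @staticmethod
    def _sites(rng, n, child_mode):
        """Trio + 20 background samples at n biallelic sites."""
        sites = []
        for i in range(n):
            p = rng.uniform(0.1, 0.9)
            def draw_gt():
                return tuple(sorted(rng.binomial(1, p, size=2)))
            f, m = draw_gt(), draw_gt()
            if child_mode == "offspring":
                c = tuple(sorted((f[rng.integers(2)], m[rng.integers(2)])))
            else:
                c = draw_gt()
            calls = {"dad": SampleCall(gt=f, dp=45),
                     "mum": SampleCall(gt=m, dp=45),
                     "kid": SampleCall(gt=c, dp=45)}
            for b in range(20):
                calls[f"bg{b}"] = SampleCall(gt=draw_gt(), dp=45)
            sites.append(SiteRecord(chrom="chr1", pos=i + 1, ref="A", alt="G",
                                    calls=calls))
        return sites

    def test_true_offspring_consistent_with_zero_opposing_homozygotes(self):
        rng = np.random.default_rng(1)
        sites = self._sites(rng, 2000, "offspring")
        reports = verify_pedigree(sites, TRIO)
        for rep in reports:
            assert rep.status == "consistent"
            assert rep.opposing_homozygote_rate == 0.0
            assert rep.z1 > 0.6

    def test_unrelated_child_flagged(self):
        rng = np.random.default_rng(2)
        sites = self._sites(rng, 2000, "unrelated")
        reports = verify_pedigree(sites, TRIO)
        for rep in reports:
            assert rep.status == "inconsistent"
            assert rep.opposing_homozygote_rate > 0.01

    def test_insufficient_data_status(self):
        rng = np.random.default_rng(3)
        sites = self._sites(rng, 50, "offspring")
        reports = verify_pedigree(sites, TRIO)
        assert all(r.status == "insufficient_data" for r in reports)

    def test_mislabeled_mother_flags_exactly_that_pair(self):
        """Swap the mother for an unrelated sample: only her pair is flagged."""
        rng = np.random.default_rng(4)
        sites = self._sites(rng, 2000, "offspring")
        for s in sites:
            p = (s.calls["bg0"].gt)  # unrelated stand-in
            s.calls["mum"] = SampleCall(gt=p, dp=45)
        reports = verify_pedigree(sites, TRIO)
        by_parent = {r.pair[0]: r for r in reports}
        assert by_parent["dad"].status == "consistent"
        assert by_parent["mum"].status == "inconsistent"


class TestRecall:
    def test_full_recall_on_error_free_data_without_ab_filter(self, clean_sim):
        """Every planted post-PGC DNM survives the funnel when AB is off."""
        filt = FilterConfig(ab_filter_enabled=False)
        cands = call_candidates(clean_sim.records, clean_sim.trios, filt)
        passing = [c for c in cands if c.passed_filters]
        validate_candidates(passing, clean_sim.evidence, filt)
        curated = {(c.trio.child, c.chrom, c.pos)
                   for c in passing if c.validation == "validated"}
        planted = [
            (off, d.chrom, d.pos)
            for d in clean_sim.truth.planted_dnms if not d.pre_pgc
            for off in d.offspring
        ]
        assert planted, "fixture must plant post-PGC DNMs"
        missed = [p for p in planted if p not in curated]
        assert missed == []
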