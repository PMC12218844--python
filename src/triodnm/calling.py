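"""Mendelian-violation detection and the DNM filter cascade.

A candidate de novo mutation is a site where both parents are homozygous
reference and the child is heterozygous. Candidates then pass a site-level
hard-filter stage (GATK-style INFO thresholds), an individual-level stage
(trio depth window, child allelic balance, genotype quality, parental
alternate reads), and finally a read-evidence validation that stands in for
visual curation and yields the false discovery rate. The same primitives
provide the callable genome size and the allelic-balance false negative
rate that enter the rate estimators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import (
    CallableSummary,
    DnmCandidate,
    ReadEvidence,
    SampleCall,
    SiteRecord,
    Trio,
)

log = logging.getLogger("triodnm")


@dataclass
class FilterConfig:
    """Thresholds of the site and individual filter stages.

    Site thresholds follow the published GATK germline SNV hard-filter
    recommendations; the individual stage applies the trio depth window
    0.5*DP_trio < DP_child < 2*DP_trio, the child allelic-balance window
    (removal outside [ab_low, ab_high], endpoints pass), a minimum GQ for
    all trio members, and a cap on parental reads carrying the child's
    variant. All values are overridable.
    """

    min_qd: float = 2.0
    max_fs: float = 60.0
    min_mq: float = 40.0
    max_sor: float = 3.0
    min_mq_rank_sum: float = -12.5
    min_read_pos_rank_sum: float = -8.0
    min_gq: int = 20
    ab_low: float = 0.3
    ab_high: float = 0.7
    ab_filter_enabled: bool = True
    ab_applies_to_parents: bool = False
    depth_low_mult: float = 0.5
    depth_high_mult: float = 2.0
    max_parental_alt_reads: int = 1
    missing_info_passes: bool = True
    min_validation_child_support: int = 2
    max_validation_parental_reads: int = 1
    chromosome_blacklist: tuple[str, ...] = ("chrY", "chrXIX")

    def __post_init__(self) -> None:
        if not self.ab_low < self.ab_high:
            raise ValueError("ab_low must be < ab_high")
        if not 0 < self.depth_low_mult < self.depth_high_mult:
            raise ValueError("depth multipliers must satisfy 0 < low < high")


# ---------------------------------------------------------------------------
# Pedigree verification
# ---------------------------------------------------------------------------

@dataclass
class RelatednessReport:
    trio: Trio
    pair: tuple[str, str]
    n_sites: int
    opposing_homozygote_rate: float
    z0: float
    z1: float
    z2: float
    status: str  # consistent | inconsistent | insufficient_data


def _ibs_expectations(p: np.ndarray) -> np.ndarray:
    """Expected IBS-state probabilities given IBD state (method of moments).

    Rows: IBS 0/1/2 counts expected under IBD 0, 1, 2 at allele frequency p.
    """
    q = 1.0 - p
    e = np.empty((3, 3, p.size))
    e[0, 0] = 2 * p**2 * q**2
    e[0, 1] = 4 * p**3 * q + 4 * p * q**3
    e[0, 2] = p**4 + q**4 + 4 * p**2 * q**2
    e[1, 0] = 0.0
    e[1, 1] = 2 * p**2 * q + 2 * p * q**2
    e[1, 2] = p**3 + q**3 + p**2 * q + p * q**2
    e[2, 0] = 0.0
    e[2, 1] = 0.0
    e[2, 2] = 1.0
    return e.sum(axis=2)  # (ibd, ibs) summed over sites


def verify_pedigree(
    sites: Iterable[SiteRecord],
    trio: Trio,
    min_informative: int = 200,
    z1_tolerance: float = 0.35,
) -> list[RelatednessReport]:
    """Confirm parent-offspring relationships from genotype data.

    For each parent-child pair, reports the opposing-homozygote rate and
    method-of-moments estimates of the IBD-sharing coefficients (Z0, Z1,
    Z2), which for a true parent-offspring pair are close to (0, 1, 0). A
    pair whose Z1 deviates from 1 beyond ``z1_tolerance`` is flagged
    inconsistent; too few informative sites yields an explicit
    insufficient-data status.
    """
    usable: list[tuple[float, int, int, int]] = []  # (p_alt, g_f, g_m, g_c)
    for site in sites:
        if site.alt is None:
            continue
        calls = [site.calls.get(m) for m in trio.members]
        if any(c is None or c.gt is None for c in calls):
            continue
        dosages = [sum(c.gt) for c in calls]
        all_gts = [sum(c.gt) for c in site.calls.values() if c.gt is not None]
        p_alt = float(np.mean(all_gts)) / 2.0 if all_gts else 0.0
        if 0.0 < p_alt < 1.0:
            usable.append((p_alt, *dosages))

    reports = []
    for parent in (trio.father, trio.mother):
        pi = 1 if parent == trio.father else 2
        pairs = [(u[0], (u[pi], u[3])) for u in usable]
        n = len(pairs)
        if n < min_informative:
            reports.append(RelatednessReport(
                trio=trio, pair=(parent, trio.child), n_sites=n,
                opposing_homozygote_rate=float("nan"),
                z0=float("nan"), z1=float("nan"), z2=float("nan"),
                status="insufficient_data",
            ))
            continue
        freqs = np.array([p for p, _ in pairs])
        ibs_counts = np.zeros(3)
        opposing = 0
        for _, (gp, gc) in pairs:
            if {gp, gc} == {0, 2}:
                opposing += 1
                ibs = 0
            elif gp == gc:
                ibs = 2
            else:
                ibs = 1
            ibs_counts[ibs] += 1
        exp = _ibs_expectations(freqs)  # (ibd, ibs)
        z0 = ibs_counts[0] / exp[0, 0] if exp[0, 0] > 0 else 0.0
        z1 = (ibs_counts[1] - z0 * exp[0, 1]) / exp[1, 1] if exp[1, 1] > 0 else 0.0
        z2 = (ibs_counts[2] - z0 * exp[0, 2] - z1 * exp[1, 2]) / n
        z0, z1, z2 = (max(0.0, z) for z in (z0, z1, z2))
        tot = z0 + z1 + z2
        if tot > 0:
            z0, z1, z2 = z0 / tot, z1 / tot, z2 / tot
        status = "consistent" if abs(z1 - 1.0) <= z1_tolerance else "inconsistent"
        reports.append(RelatednessReport(
            trio=trio, pair=(parent, trio.child), n_sites=n,
            opposing_homozygote_rate=opposing / n,
            z0=z0, z1=z1, z2=z2, status=status,
        ))
    return reports


# ---------------------------------------------------------------------------
# Mendelian violations
# ---------------------------------------------------------------------------

def find_mendelian_violations(
    site: SiteRecord, trio: Trio
) -> Optional[DnmCandidate]:
    """Candidate DNM iff father 0/0, mother 0/0 and child 0/1.

    Every other trio configuration — including back-mutation-like patterns
    where the parents carry the alternate allele — yields nothing; a missing
    genotype in any member disqualifies the site.
    """
    if site.alt is None:
        return None
    f = site.calls.get(trio.father)
    m = site.calls.get(trio.mother)
    c = site.calls.get(trio.child)
    if f is None or m is None or c is None:
        return None
    if f.gt is None or m.gt is None or c.gt is None:
        return None
    if f.is_hom_ref and m.is_hom_ref and c.is_het:
        return DnmCandidate(
            trio=trio, chrom=site.chrom, pos=site.pos,
            ref=site.ref, alt=site.alt,
        )
    return None


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

_SITE_CHECKS = (
    ("QD", lambda v, c: v >= c.min_qd),
    ("FS", lambda v, c: v <= c.max_fs),
    ("MQ", lambda v, c: v >= c.min_mq),
    ("SOR", lambda v, c: v <= c.max_sor),
    ("MQRankSum", lambda v, c: v >= c.min_mq_rank_sum),
    ("ReadPosRankSum", lambda v, c: v >= c.min_read_pos_rank_sum),
)


def apply_site_filters(
    site: SiteRecord, config: FilterConfig
) -> tuple[bool, Optional[str]]:
    """Hard site filters on INFO statistics; first violation is the reason.

    A statistic absent from INFO passes with a warning under the default
    missing-passes policy (rank sums are routinely undefined at sites where
    one genotype class is empty) or fails the site when the policy is
    strict.
    """
    for name, ok in _SITE_CHECKS:
        if name not in site.info:
            if config.missing_info_passes:
                log.debug("site %s:%d missing INFO %s, passing", site.chrom,
                          site.pos, name)
                continue
            return False, f"missing_{name}"
        if not ok(site.info[name], config):
            return False, name
    return True, None


def _trio_depth(site: SiteRecord, trio: Trio) -> float:
    """DP_trio: mean depth of the three trio members at the site."""
    dps = [site.calls[m].dp for m in trio.members if m in site.calls]
    return float(np.mean(dps)) if dps else 0.0


def depth_window_ok(site: SiteRecord, trio: Trio, config: FilterConfig) -> bool:
    child = site.calls.get(trio.child)
    if child is None or child.dp == 0:
        return False
    dp_trio = _trio_depth(site, trio)
    return (config.depth_low_mult * dp_trio < child.dp
            < config.depth_high_mult * dp_trio)


def apply_individual_filters(
    candidate: DnmCandidate, site: SiteRecord, config: FilterConfig
) -> DnmCandidate:
    """Trio-level filters appended to the candidate's filter trail.

    Checks, in order: child depth inside the trio depth window; child
    allelic balance within [ab_low, ab_high] (inclusive endpoints pass);
    genotype quality of all three members; and at most
    ``max_parental_alt_reads`` parental reads carrying the child's variant.
    The trail records every check so the funnel stays auditable.
    """
    trio = candidate.trio
    trail = candidate.filter_trail
    child = site.calls[trio.child]

    trail.append(("depth", depth_window_ok(site, trio, config)))

    if config.ab_filter_enabled:
        members = [trio.child]
        if config.ab_applies_to_parents:
            members.extend([trio.father, trio.mother])
        ab_ok = True
        for m in members:
            call = site.calls.get(m)
            if call is None or call.ad is None:
                log.debug("no AD for %s at %s:%d; AB check skipped", m,
                          site.chrom, site.pos)
                continue
            if m == trio.child:
                ab = call.allelic_balance
                if ab is None or not (config.ab_low <= ab <= config.ab_high):
                    ab_ok = False
        trail.append(("allelic_balance", ab_ok))

    gq_ok = all(
        site.calls[m].gq is not None and site.calls[m].gq >= config.min_gq
        for m in trio.members if m in site.calls
    )
    trail.append(("GQ", gq_ok))

    parental_alt = 0
    for m in (trio.father, trio.mother):
        call = site.calls.get(m)
        if call is not None and call.ad is not None:
            parental_alt += call.ad[1]
    trail.append(("parental_reads", parental_alt <= config.max_parental_alt_reads))
    return candidate


def call_candidates(
    sites: Iterable[SiteRecord],
    trios: Sequence[Trio],
    config: FilterConfig,
    funnel: Optional[dict] = None,
) -> list[DnmCandidate]:
    """Full detection funnel over a site stream for a set of trios.

    Returns every Mendelian-violation candidate with its complete filter
    trail; callers select the passing subset via ``passed_filters``. A
    funnel dict, if supplied, accumulates stage counts.
    """
    if funnel is None:
        funnel = {}
    funnel.setdefault("sites", 0)
    funnel.setdefault("violations", 0)
    funnel.setdefault("site_filter_fail", 0)
    funnel.setdefault("individual_filter_fail", 0)
    funnel.setdefault("passed", 0)
    blacklist = set(config.chromosome_blacklist)
    out: list[DnmCandidate] = []
    for site in sites:
        funnel["sites"] += 1
        if site.chrom in blacklist:
            continue
        site_ok, reason = apply_site_filters(site, config)
        for trio in trios:
            cand = find_mendelian_violations(site, trio)
            if cand is None:
                continue
            funnel["violations"] += 1
            cand.filter_trail.append((f"site:{reason}" if not site_ok else "site",
                                      site_ok))
            if not site_ok:
                funnel["site_filter_fail"] += 1
            apply_individual_filters(cand, site, config)
            if cand.passed_filters:
                funnel["passed"] += 1
            elif site_ok:
                funnel["individual_filter_fail"] += 1
            out.append(cand)
    return out


# ---------------------------------------------------------------------------
# Validation (automated stand-in for visual curation)
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    n_candidates: int
    n_rejected: int
    fdr: float
    by_reason: dict[str, int] = field(default_factory=dict)


def validate_candidates(
    candidates: Sequence[DnmCandidate],
    evidence: Sequence[ReadEvidence],
    config: FilterConfig,
) -> ValidationReport:
    """Read-evidence validation of filter-passing candidates, yielding FDR.

    A candidate is rejected when fragments show more than
    ``max_validation_parental_reads`` parental reads carrying its variant,
    or fewer than ``min_validation_child_support`` child reads carrying it.
    Candidates with no evidence at all are conservatively rejected as
    unvalidatable. FDR = rejected / all candidates entering validation.
    """
    by_locus: dict[tuple[str, int], list[ReadEvidence]] = {}
    for frag in evidence:
        for chrom, pos, _ in frag.observations:
            by_locus.setdefault((chrom, pos), []).append(frag)

    passing = [c for c in candidates if c.passed_filters]
    n_rejected = 0
    by_reason: dict[str, int] = {}
    for cand in passing:
        frags = by_locus.get((cand.chrom, cand.pos), [])
        child_support = 0
        parental_support = 0
        seen_any = False
        for frag in frags:
            obs_here = [b for c2, p2, b in frag.observations
                        if (c2, p2) == (cand.chrom, cand.pos)]
            if len(set(obs_here)) > 1:
                log.debug("fragment %s internally inconsistent at %s:%d; dropped",
                          frag.fragment_id, cand.chrom, cand.pos)
                continue
            if not obs_here:
                continue
            base = obs_here[0]
            if frag.sample == cand.trio.child:
                seen_any = True
                if base == cand.alt:
                    child_support += 1
            elif frag.sample in (cand.trio.father, cand.trio.mother):
                seen_any = True
                if base == cand.alt:
                    parental_support += 1
        if not seen_any:
            cand.validation = "unvalidatable"
            n_rejected += 1
        elif parental_support > config.max_validation_parental_reads:
            cand.validation = "rejected_parental_reads"
            n_rejected += 1
        elif child_support < config.min_validation_child_support:
            cand.validation = "rejected_low_support"
            n_rejected += 1
        else:
            cand.validation = "validated"
        if cand.validation != "validated":
            by_reason[cand.validation] = by_reason.get(cand.validation, 0) + 1
    n = len(passing)
    return ValidationReport(
        n_candidates=n, n_rejected=n_rejected,
        fdr=n_rejected / n if n else 0.0, by_reason=by_reason,
    )


# ---------------------------------------------------------------------------
# Callable genome size and FNR
# ---------------------------------------------------------------------------

def compute_callable_size(
    sites: Iterable[SiteRecord],
    trio: Trio,
    config: FilterConfig,
    autosome_total: Optional[float] = None,
) -> CallableSummary:
    """Count sites callable for this trio's offspring.

    A site is callable when the child depth lies inside the trio depth
    window and both parents are homozygous (reference or alternate). With a
    sparse depth-survey stream, pass ``autosome_total`` to scale the pass
    fraction up to the genome: CS = pass_fraction * autosome_total.
    """
    n_total = 0
    n_pass = 0
    for site in sites:
        if site.chrom in set(config.chromosome_blacklist):
            continue
        n_total += 1
        f = site.calls.get(trio.father)
        m = site.calls.get(trio.mother)
        if f is None or m is None or f.gt is None or m.gt is None:
            continue
        if f.gt[0] != f.gt[1] or m.gt[0] != m.gt[1]:
            continue
        if depth_window_ok(site, trio, config):
            n_pass += 1
    if n_total == 0:
        log.warning("empty site stream for callable size of %s", trio.child)
        return CallableSummary(offspring=trio.child, cs=0.0,
                               autosome_total=autosome_total or 0.0)
    if autosome_total is None:
        return CallableSummary(offspring=trio.child, cs=float(n_pass),
                               autosome_total=float(n_total))
    return CallableSummary(
        offspring=trio.child,
        cs=n_pass / n_total * autosome_total,
        autosome_total=autosome_total,
    )


@dataclass
class FnrEstimate:
    trio: Trio
    n_obligate_het: int
    n_removed: int
    status: str  # ok | unavailable

    @property
    def fnr(self) -> float:
        if self.status != "ok":
            raise ValueError("FNR unavailable: too few obligate-het sites")
        return self.n_removed / self.n_obligate_het


def estimate_fnr(
    sites: Iterable[SiteRecord],
    trio: Trio,
    config: FilterConfig,
    min_sites: int = 50,
) -> FnrEstimate:
    """Allelic-balance false negative rate from obligate heterozygotes.

    At sites where one parent is 0/0 and the other 1/1 the child is a true
    heterozygote by inheritance; the FNR is the fraction of those children
    whose allelic balance falls outside the AB window (or who lack reads).
    """
    n = 0
    removed = 0
    for site in sites:
        if site.alt is None or site.chrom in set(config.chromosome_blacklist):
            continue
        f = site.calls.get(trio.father)
        m = site.calls.get(trio.mother)
        c = site.calls.get(trio.child)
        if f is None or m is None or c is None:
            continue
        if f.gt is None or m.gt is None:
            continue
        if not ((f.is_hom_ref and m.is_hom_alt) or (f.is_hom_alt and m.is_hom_ref)):
            continue
        n += 1
        ab = c.allelic_balance
        if ab is None or not (config.ab_low <= ab <= config.ab_high):
            removed += 1
    status = "ok" if n >= min_sites else "unavailable"
    return FnrEstimate(trio=trio, n_obligate_het=n, n_removed=removed, status=status)


# ---------------------------------------------------------------------------
# Sharing among full sibs
# ---------------------------------------------------------------------------

@dataclass
class SharingReport:
    n_unique: int
    n_shared: int  # unique DNMs carried by >= 2 sibs
    size_histogram: dict[int, int]

    @property
    def shared_percentage(self) -> float:
        return 100.0 * self.n_shared / self.n_unique if self.n_unique else 0.0


def group_shared(
    candidates: Sequence[DnmCandidate],
) -> tuple[list[list[DnmCandidate]], SharingReport]:
    """Collapse identical calls across full sibs into unique DNM events.

    Candidates agreeing in (family, chrom, pos, alt) form one unique DNM;
    the same position with different alternate alleles stays distinct.
    Returns the groups (each a list of per-offspring candidates) and a
    sharing summary.
    """
    groups: dict[tuple, list[DnmCandidate]] = {}
    for cand in candidates:
        groups.setdefault(cand.key, []).append(cand)
    hist: dict[int, int] = {}
    out = []
    for key, members in sorted(groups.items()):
        gid = f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"
        for m in members:
            m.shared_group = gid if len(members) > 1 else None
        hist[len(members)] = hist.get(len(members), 0) + 1
        out.append(members)
    n_unique = len(out)
    n_shared = sum(1 for g in out if len(g) > 1)
    return out, SharingReport(n_unique=n_unique, n_shared=n_shared,
                              size_histogram=hist)
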