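"""Read-backed parent-of-origin phasing of de novo mutations.

A DNM is phased by finding heterozygous child sites near it whose parental
genotypes pin each child allele to one parent (informative sites), then
letting sequencing fragments that carry both the mutant allele and an
informative-site allele vote for the parent whose haplotype the mutation
rides on. The paternal fraction p of phased DNMs gives the
paternal-to-maternal odds alpha = p / (1 - p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .model import DnmCandidate, ReadEvidence, SiteRecord, Trio
from .spectrum import chi_square_gof, ChiSquareResult

log = logging.getLogger("triodnm")


@dataclass
class InformativeSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    allele_parent: dict[int, str]  # allele index (0 ref / 1 alt) -> parent


@dataclass
class PhaseConfig:
    window: int = 500  # bp around the DNM searched for informative sites
    min_support: int = 1  # fragments required for the winning parent
    max_conflict: int = 0  # fragments tolerated for the other parent


@dataclass
class PhaseResult:
    dnm_id: str
    origin: str  # paternal | maternal | unknown
    paternal_fragments: int
    maternal_fragments: int
    informative_sites_used: int


def _allele_origin(f_gt, m_gt) -> Optional[dict[int, str]]:
    """Which parent contributed each allele of a heterozygous child.

    Enumerates the consistent (paternal allele, maternal allele)
    assignments of a 0/1 child; the site is informative only when exactly
    one assignment survives, which requires at least one homozygous parent.
    """
    def can_give(gt, allele):
        return allele in gt
    assignments = [
        (pa, ma)
        for pa, ma in ((0, 1), (1, 0))
        if can_give(f_gt, pa) and can_give(m_gt, ma)
    ]
    if len(assignments) != 1:
        return None
    pa, ma = assignments[0]
    return {pa: "paternal", ma: "maternal"}


def find_informative_sites(
    dnm: DnmCandidate,
    sites: Sequence[SiteRecord],
    window: int = 500,
) -> list[InformativeSite]:
    """Heterozygous child sites near the DNM with a unique allele-to-parent map."""
    out = []
    trio = dnm.trio
    for site in sites:
        if site.alt is None or site.chrom != dnm.chrom:
            continue
        if abs(site.pos - dnm.pos) > window or site.pos == dnm.pos:
            continue
        f = site.calls.get(trio.father)
        m = site.calls.get(trio.mother)
        c = site.calls.get(trio.child)
        if f is None or m is None or c is None:
            continue
        if f.gt is None or m.gt is None or c.gt is None or not c.is_het:
            continue
        mapping = _allele_origin(f.gt, m.gt)
        if mapping is not None:
            out.append(InformativeSite(
                chrom=site.chrom, pos=site.pos, ref=site.ref, alt=site.alt,
                allele_parent=mapping,
            ))
    return out


def phase_dnm(
    dnm: DnmCandidate,
    informative: Sequence[InformativeSite],
    evidence: Sequence[ReadEvidence],
    config: Optional[PhaseConfig] = None,
) -> PhaseResult:
    """Vote-based origin call for one DNM.

    Each child fragment observing the DNM alternate allele together with an
    allele at an informative site votes for the parent that allele maps to.
    The origin is called when the winning parent has at least
    ``min_support`` votes and the other at most ``max_conflict``; anything
    else stays unknown. Fragments with contradictory duplicate observations
    at a site are discarded.
    """
    if config is None:
        config = PhaseConfig()
    dnm_id = f"{dnm.trio.child}:{dnm.chrom}:{dnm.pos}"
    info_at = {(s.chrom, s.pos): s for s in informative}
    votes = {"paternal": 0, "maternal": 0}
    used_sites = set()
    for frag in evidence:
        if frag.sample != dnm.trio.child:
            continue
        by_pos: dict[tuple[str, int], set[str]] = {}
        for chrom, pos, base in frag.observations:
            by_pos.setdefault((chrom, pos), set()).add(base)
        if any(len(b) > 1 for b in by_pos.values()):
            log.debug("discarding internally inconsistent fragment %s",
                      frag.fragment_id)
            continue
        dnm_obs = by_pos.get((dnm.chrom, dnm.pos))
        if dnm_obs is None or next(iter(dnm_obs)) != dnm.alt:
            continue
        for key, bases in by_pos.items():
            site = info_at.get(key)
            if site is None:
                continue
            base = next(iter(bases))
            if base == site.ref:
                allele = 0
            elif base == site.alt:
                allele = 1
            else:
                continue
            votes[site.allele_parent[allele]] += 1
            used_sites.add(key)
    pat, mat = votes["paternal"], votes["maternal"]
    origin = "unknown"
    if pat >= config.min_support and mat <= config.max_conflict:
        origin = "paternal"
    elif mat >= config.min_support and pat <= config.max_conflict:
        origin = "maternal"
    return PhaseResult(
        dnm_id=dnm_id, origin=origin, paternal_fragments=pat,
        maternal_fragments=mat, informative_sites_used=len(used_sites),
    )


@dataclass
class AlphaEstimate:
    alpha: float  # paternal/maternal odds; inf when p = 1
    ci_low: float
    ci_high: float
    paternal_fraction: float
    fraction_ci: tuple[float, float]
    n_phased: int
    infinite: bool = False


def compute_alpha(
    results: Sequence[PhaseResult], ci_method: str = "wilson"
) -> AlphaEstimate:
    """Paternal-to-maternal odds from phased DNMs with a transformed binomial CI.

    alpha = p / (1 - p) where p is the paternal fraction among phased DNMs;
    the CI transforms a binomial interval for p (Wilson by default).
    """
    phased = [r for r in results if r.origin != "unknown"]
    if not phased:
        raise ValueError("no phased DNMs: alpha undefined")
    n = len(phased)
    k = sum(1 for r in phased if r.origin == "paternal")
    p = k / n
    lo, hi = proportion_confint(k, n, alpha=0.05, method=ci_method)
    odds = lambda x: x / (1.0 - x) if x < 1.0 else float("inf")
    return AlphaEstimate(
        alpha=odds(p), ci_low=odds(lo), ci_high=odds(hi),
        paternal_fraction=p, fraction_ci=(float(lo), float(hi)),
        n_phased=n, infinite=p >= 1.0,
    )


@dataclass
class SexBiasReport:
    partition: str
    maternal: int
    paternal: int
    test: Optional[ChiSquareResult]
    status: str  # ok | not_testable


def sex_bias_tests(
    results: Sequence[PhaseResult],
    shared_ids: set[str],
    cpg_ids: Optional[set[str]] = None,
) -> list[SexBiasReport]:
    """1:1 chi-square tests for shared/non-shared (and CpG) phased DNMs."""
    phased = [r for r in results if r.origin != "unknown"]
    partitions = {
        "shared": [r for r in phased if r.dnm_id in shared_ids],
        "non_shared": [r for r in phased if r.dnm_id not in shared_ids],
    }
    if cpg_ids is not None:
        partitions["cpg"] = [r for r in phased if r.dnm_id in cpg_ids]
        partitions["non_cpg"] = [r for r in phased if r.dnm_id not in cpg_ids]
    out = []
    for name, rs in partitions.items():
        mat = sum(1 for r in rs if r.origin == "maternal")
        pat = sum(1 for r in rs if r.origin == "paternal")
        if mat + pat == 0:
            out.append(SexBiasReport(partition=name, maternal=0, paternal=0,
                                     test=None, status="not_testable"))
            continue
        out.append(SexBiasReport(
            partition=name, maternal=mat, paternal=pat,
            test=chi_square_gof([mat, pat], [0.5, 0.5]), status="ok",
        ))
    return out
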