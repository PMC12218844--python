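"""Synthetic trio-sequencing data with a known mutational truth set.

The generator emulates the statistical structure a trio-based de novo
mutation (DNM) study rests on: families of full sibs sequenced to high
coverage, parental polymorphism, germline mutations planted at a fixed
per-generation rate with CpG hypermutability, a paternal/maternal origin
ratio, pre-PGC (primordial germ cell) events shared among sibs, Poisson
depth, binomial allele sampling with sequencing error, and read fragments
linking mutations to nearby heterozygous sites for read-backed phasing.

Two scales are provided:

* :func:`simulate` — a per-base simulation writing VCF/FASTA/TSV outputs,
  used for end-to-end pipeline tests on megabase genomes.
* :func:`simulate_event_level` — event-count simulation (mutation counts and
  positions only) for rate-estimator recovery experiments at full callable
  size (hundreds of Mb), where a per-base genome would be pointless.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    Transcript,
    write_bed,
    write_fasta,
    write_pedigree,
    write_read_evidence,
    write_vcf,
)
from .model import (
    PlantedDnm,
    ReadEvidence,
    SampleCall,
    SiteRecord,
    Trio,
    TruthSet,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")
A, C, G, T = 0, 1, 2, 3
_IDX = {b: i for i, b in enumerate("ACGT")}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study design and noise model of the synthetic cohort.

    Defaults mirror the cohort the pipeline targets: 4 pedigrees of 10
    full-sib offspring sequenced to 45x, a per-generation point mutation
    rate of 5.11e-9/bp, no sex bias in mutation origin (alpha = 1), and a
    tenfold CpG rate elevation. Chromosome lengths are scaled megabases;
    rates are per-bp so results scale with ``callable_length``.
    """

    n_families: int = 4
    n_offspring_per_family: int = 10
    callable_length: int = 1_000_000  # bp per chromosome
    n_chromosomes: int = 4
    gc_fraction: float = 0.44
    cpg_island_spec: Optional[list[list[tuple[int, int, float]]]] = None
    mu_true: float = 5.11e-9
    alpha_true: float = 1.0  # paternal/maternal odds of DNM origin
    shared_fraction: float = 0.1  # fraction of mutational mass arising pre-PGC
    cpg_rate_multiplier: float = 10.0
    mean_depth: float = 45.0
    seq_error_rate: float = 1e-3
    polymorphism_rate: float = 1e-3  # parental heterozygosity per bp
    seed: int = 0
    # noise/plumbing knobs
    hom_alt_factor: float = 0.25  # hom-alt parental sites per het site
    fp_per_offspring: float = 0.5  # injected artifact candidates (Poisson mean)
    info_fail_fraction: float = 0.5  # artifact sites given a failing INFO stat
    survey_stride: int = 997  # depth-survey sampling stride (bp)
    fragment_length: int = 500  # read-evidence linking range (bp)
    ts_fraction: float = 0.55  # transition share of non-CpG events
    cpg_deamination_prob: float = 0.7  # C>T share at CpG events
    cpg_depletion: float = 0.75  # background CpG -> GpC swap probability

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "shared_fraction", "seq_error_rate",
                     "polymorphism_rate", "ts_fraction", "cpg_deamination_prob",
                     "cpg_depletion", "info_fail_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mu_true <= 0:
            raise ValueError("mu_true must be > 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.alpha_true <= 0:
            raise ValueError("alpha_true must be > 0")
        if self.cpg_island_spec is not None:
            if len(self.cpg_island_spec) != self.n_chromosomes:
                raise ValueError("cpg_island_spec needs one list per chromosome")
            for spec in self.cpg_island_spec:
                ivs = sorted(spec)
                for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
                    if s2 < e1:
                        raise ValueError("overlapping CpG island intervals")
                for s, e, gcf in ivs:
                    if not (0 <= s < e <= self.callable_length):
                        raise ValueError("island interval outside chromosome")
                    if not 0.3 <= gcf <= 1.0:
                        raise ValueError("island GC must be in [0.3, 1]")

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def genome_length(self) -> int:
        return self.callable_length * self.n_chromosomes

    def island_spec(self) -> list[list[tuple[int, int, float]]]:
        """Explicit island plan; by default two GC-rich islands per chromosome."""
        if self.cpg_island_spec is not None:
            return [sorted(s) for s in self.cpg_island_spec]
        L = self.callable_length
        if L < 10_000:
            return [[] for _ in range(self.n_chromosomes)]
        spec = []
        for _ in range(self.n_chromosomes):
            spec.append([
                (int(L * 0.25), int(L * 0.25) + 600, 0.65),
                (int(L * 0.65), int(L * 0.65) + 900, 0.68),
            ])
        return spec

    def rng(self, *stream: int) -> np.random.Generator:
        """Deterministic per-stage generator derived from the config seed."""
        return np.random.default_rng([self.seed, *stream])


def make_pedigree(config: SimConfig) -> list[Trio]:
    trios = []
    for i in range(config.n_families):
        fam = f"F{i + 1}"
        for j in range(config.n_offspring_per_family):
            trios.append(
                Trio(family=fam, father=f"{fam}_father", mother=f"{fam}_mother",
                     child=f"{fam}_o{j + 1:02d}")
            )
    return trios


def sample_order(config: SimConfig) -> list[str]:
    out = []
    for i in range(config.n_families):
        fam = f"F{i + 1}"
        out.extend([f"{fam}_father", f"{fam}_mother"])
        out.extend(f"{fam}_o{j + 1:02d}" for j in range(config.n_offspring_per_family))
    return out


# ---------------------------------------------------------------------------
# Reference sequence
# ---------------------------------------------------------------------------

def _iid_sequence(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _island_sequence(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """CpG-island sequence: CG dinucleotide blocks at rate q on an iid floor.

    With block probability q the expected GC equals q + (1-q)*gc', so the
    iid floor is adjusted to hit the requested island GC while the explicit
    CG blocks push observed/expected CpG well above the detection threshold.
    """
    q = 0.2
    gc_rest = (gc - q) / (1 - q)
    if not 0 <= gc_rest <= 1:
        raise ValueError("island GC incompatible with CpG block rate")
    n_blocks = n // 2
    is_cg = rng.random(n_blocks) < q
    seq = np.empty(n_blocks * 2, dtype=np.uint8)
    rest = _iid_sequence(n_blocks * 2, gc_rest, rng)
    seq[0::2] = np.where(is_cg, C, rest[0::2])
    seq[1::2] = np.where(is_cg, G, rest[1::2])
    if n % 2:
        seq = np.concatenate([seq, _iid_sequence(1, gc_rest, rng)])
    return seq


def generate_reference(config: SimConfig) -> dict[str, np.ndarray]:
    """Per-chromosome base arrays (uint8 over ACGT=0123).

    The background is iid at ``gc_fraction`` with CpG depletion applied by
    swapping a fraction of CG dinucleotides to GC (composition-preserving),
    mimicking the genome-wide CpG deficit of methylated genomes. Designated
    island intervals are overwritten with CpG-rich sequence.
    """
    rng = config.rng(1)
    ref: dict[str, np.ndarray] = {}
    spec = config.island_spec()
    for ci, chrom in enumerate(config.chromosomes):
        seq = _iid_sequence(config.callable_length, config.gc_fraction, rng)
        # CpG depletion: relocate the G of a CG to a distant A/T position
        # whose left neighbour is not C — composition-preserving, and no
        # new CpG can appear at either end of the exchange
        cg = np.flatnonzero((seq[:-1] == C) & (seq[1:] == G))
        if cg.size:
            chosen = cg[rng.random(cg.size) < config.cpg_depletion]
            at = np.flatnonzero((seq == A) | (seq == T))
            at = at[(at > 0) & (seq[np.maximum(at - 1, 0)] != C)]
            if at.size >= chosen.size > 0:
                partners = rng.choice(at, size=chosen.size, replace=False)
                keep = partners != chosen + 1
                chosen, partners = chosen[keep], partners[keep]
                moved = seq[partners].copy()
                seq[partners] = G
                seq[chosen + 1] = moved
        for start, end, gcf in spec[ci]:
            seq[start:end] = _island_sequence(end - start, gcf, rng)
        ref[chrom] = seq
    return ref


def reference_to_str(ref: dict[str, np.ndarray]) -> dict[str, str]:
    return {c: BASES[s].tobytes().decode() for c, s in ref.items()}


def cpg_site_mask(seq: np.ndarray) -> np.ndarray:
    """True at every base belonging to a CpG dinucleotide (C or the G)."""
    mask = np.zeros(seq.size, dtype=bool)
    cg = (seq[:-1] == C) & (seq[1:] == G)
    mask[:-1] |= cg
    mask[1:] |= cg
    return mask


# ---------------------------------------------------------------------------
# Parental genotypes and transmission
# ---------------------------------------------------------------------------

@dataclass
class FamilySites:
    """Polymorphic sites of one family on one chromosome (arrays, 0-based)."""

    pos: np.ndarray  # int64, sorted
    ref: np.ndarray  # uint8 base index
    alt: np.ndarray  # uint8 base index
    f_gt: np.ndarray  # 0 hom-ref, 1 het, 2 hom-alt
    m_gt: np.ndarray
    child_pat: np.ndarray  # (n_offspring, n_sites) alt-allele indicator
    child_mat: np.ndarray


@dataclass
class FamilyGenotypes:
    family: str
    offspring: list[str]
    sites: dict[str, FamilySites]  # per chromosome


def _alt_bases(ref: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random alternative base differing from ref."""
    shift = rng.integers(1, 4, size=ref.size).astype(np.uint8)
    return (ref + shift) % 4


def _parent_sites(L: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(L * rate)
    n = min(n, L)
    return rng.choice(L, size=n, replace=False)


def generate_parents(
    config: SimConfig, reference: dict[str, np.ndarray]
) -> dict[str, FamilyGenotypes]:
    """Place parental polymorphism and transmit alleles to each offspring.

    Each parent carries heterozygous sites at ``polymorphism_rate`` per bp
    plus hom-alt sites at ``hom_alt_factor`` times that rate; the latter
    create the obligate-heterozygote (0/0 x 1/1) sites the false-negative
    estimator feeds on. Offspring alleles are Mendelian draws per site.
    """
    rng = config.rng(2)
    n_off = config.n_offspring_per_family
    out: dict[str, FamilyGenotypes] = {}
    for i in range(config.n_families):
        fam = f"F{i + 1}"
        sites: dict[str, FamilySites] = {}
        for chrom in config.chromosomes:
            seq = reference[chrom]
            L = seq.size
            entries: dict[int, list] = {}
            for parent_idx in range(2):  # 0 father, 1 mother
                for gt_code, rate in (
                    (1, config.polymorphism_rate),
                    (2, config.polymorphism_rate * config.hom_alt_factor),
                ):
                    for p in _parent_sites(L, rate, rng):
                        e = entries.setdefault(int(p), [0, 0])
                        e[parent_idx] = gt_code
            pos = np.array(sorted(entries), dtype=np.int64)
            f_gt = np.array([entries[p][0] for p in pos], dtype=np.uint8)
            m_gt = np.array([entries[p][1] for p in pos], dtype=np.uint8)
            refb = seq[pos] if pos.size else np.empty(0, dtype=np.uint8)
            alt = _alt_bases(refb, rng)
            # transmission: one allele from each parent per offspring
            def transmit(gt: np.ndarray) -> np.ndarray:
                draws = rng.random((n_off, gt.size)) < 0.5
                return np.where(
                    gt == 2, 1, np.where(gt == 1, draws.astype(np.uint8), 0)
                ).astype(np.uint8)

            sites[chrom] = FamilySites(
                pos=pos, ref=refb, alt=alt, f_gt=f_gt, m_gt=m_gt,
                child_pat=transmit(f_gt), child_mat=transmit(m_gt),
            )
        out[fam] = FamilyGenotypes(
            family=fam,
            offspring=[f"{fam}_o{j + 1:02d}" for j in range(n_off)],
            sites=sites,
        )
    return out


# ---------------------------------------------------------------------------
# Planting de novo mutations
# ---------------------------------------------------------------------------

def _draw_alt(ref_base: int, at_cpg: bool, config: SimConfig,
              rng: np.random.Generator) -> int:
    """Mutation spectrum of planted events.

    CpG events are deamination-dominated (C>T / G>A with probability
    ``cpg_deamination_prob``); elsewhere transitions occur with probability
    ``ts_fraction`` and the two transversions split the rest evenly.
    """
    transition = (ref_base + 2) % 4
    transversions = [b for b in range(4) if b != ref_base and b != transition]
    if at_cpg and ref_base in (C, G):
        if rng.random() < config.cpg_deamination_prob:
            return T if ref_base == C else A
    if rng.random() < config.ts_fraction:
        return transition
    return transversions[rng.integers(2)]


def plant_dnms(
    config: SimConfig,
    reference: dict[str, np.ndarray],
    families: dict[str, FamilyGenotypes],
) -> TruthSet:
    """Plant germline mutations with CpG elevation, origin odds and sharing.

    Post-PGC events arrive per offspring as Poisson(2 * L_eff * mu * (1-s))
    where the effective length weighs CpG bases by ``cpg_rate_multiplier``
    and s is ``shared_fraction``. Pre-PGC events arrive per family as
    Poisson(2 * L_eff * mu * 2s) in a parent and transmit to each sib
    independently with probability 1/2, so the expected per-offspring count
    is 2 * L_eff * mu regardless of s. All events land at sites where both
    parents are homozygous reference.
    """
    rng = config.rng(3)
    cpg_pool: list[tuple[str, np.ndarray]] = []
    other_pool: list[tuple[str, np.ndarray]] = []
    n_cpg = n_other = 0
    for chrom in config.chromosomes:
        mask = cpg_site_mask(reference[chrom])
        cpg_pos = np.flatnonzero(mask)
        other_pos = np.flatnonzero(~mask)
        cpg_pool.append((chrom, cpg_pos))
        other_pool.append((chrom, other_pos))
        n_cpg += cpg_pos.size
        n_other += other_pos.size
    w_cpg = n_cpg * config.cpg_rate_multiplier
    w_other = float(n_other)
    lam = 2.0 * config.mu_true * (w_cpg + w_other)  # per offspring per generation
    p_cpg = w_cpg / (w_cpg + w_other)
    p_pat = config.alpha_true / (1.0 + config.alpha_true)

    def draw_site(taken: set) -> tuple[str, int, bool]:
        while True:
            at_cpg = rng.random() < p_cpg
            pool = cpg_pool if at_cpg else other_pool
            sizes = np.array([p.size for _, p in pool], dtype=float)
            ci = rng.choice(len(pool), p=sizes / sizes.sum())
            chrom, positions = pool[ci]
            pos = int(positions[rng.integers(positions.size)])
            if (chrom, pos) not in taken:
                return chrom, pos, at_cpg

    planted: list[PlantedDnm] = []
    counts: dict[str, int] = {}
    for fam_id, fam in families.items():
        taken = {
            (chrom, int(p))
            for chrom, fs in fam.sites.items()
            for p in fs.pos
        }
        for off in fam.offspring:
            counts.setdefault(off, 0)
        # post-PGC: private to one offspring
        s = config.shared_fraction
        for off in fam.offspring:
            n_events = rng.poisson(lam * (1.0 - s))
            for _ in range(n_events):
                chrom, pos, at_cpg = draw_site(taken)
                taken.add((chrom, pos))
                refb = int(reference[chrom][pos])
                alt = _draw_alt(refb, at_cpg, config, rng)
                origin = "paternal" if rng.random() < p_pat else "maternal"
                planted.append(PlantedDnm(
                    family=fam_id, offspring=(off,), chrom=chrom, pos=pos + 1,
                    ref="ACGT"[refb], alt="ACGT"[alt],
                    parent_of_origin=origin, pre_pgc=False, cpg=at_cpg,
                ))
                counts[off] += 1
        # pre-PGC: one parental event, independent 1/2 transmissions
        n_pre = rng.poisson(lam * 2.0 * s)
        for _ in range(n_pre):
            carriers = tuple(
                off for off in fam.offspring if rng.random() < 0.5
            )
            if not carriers:
                continue  # event not inherited by any sampled sib
            chrom, pos, at_cpg = draw_site(taken)
            taken.add((chrom, pos))
            refb = int(reference[chrom][pos])
            alt = _draw_alt(refb, at_cpg, config, rng)
            origin = "paternal" if rng.random() < p_pat else "maternal"
            planted.append(PlantedDnm(
                family=fam_id, offspring=carriers, chrom=chrom, pos=pos + 1,
                ref="ACGT"[refb], alt="ACGT"[alt],
                parent_of_origin=origin, pre_pgc=True, cpg=at_cpg,
            ))
            for off in carriers:
                counts[off] += 1
    return TruthSet(planted_dnms=planted, per_offspring_true_count=counts)


# ---------------------------------------------------------------------------
# Observation model
# ---------------------------------------------------------------------------

def _genotype_call(
    dp: np.ndarray, alt: np.ndarray, eps: float
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood genotype (0/1/2 alt dosage) and phred GQ."""
    qs = np.array([eps / 3.0, 0.5, 1.0 - eps / 3.0])
    ll = np.empty((3,) + dp.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        for g, q in enumerate(qs):
            ll[g] = alt * np.log(q) + (dp - alt) * np.log1p(-q)
    ll = np.nan_to_num(ll, nan=-np.inf, neginf=-1e12)
    order = np.argsort(ll, axis=0)
    best = order[-1]
    second_ll = np.take_along_axis(ll, order[-2][None], axis=0)[0]
    best_ll = np.take_along_axis(ll, order[-1][None], axis=0)[0]
    gq = np.clip(np.rint(10.0 / np.log(10.0) * (best_ll - second_ll)), 0, 99)
    return best.astype(np.uint8), gq.astype(np.int64)


def _passing_info(n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Site statistics drawn from the passing side of the default hard filters."""
    return {
        "QD": np.clip(rng.normal(22.0, 5.0, n), 2.5, 40.0),
        "FS": np.clip(np.abs(rng.normal(0.0, 3.0, n)), 0.0, 55.0),
        "MQ": np.clip(60.0 - np.abs(rng.normal(0.0, 1.5, n)), 41.0, 60.0),
        "SOR": np.clip(rng.normal(1.0, 0.4, n), 0.05, 2.8),
        "MQRankSum": np.clip(rng.normal(0.0, 1.0, n), -10.0, 10.0),
        "ReadPosRankSum": np.clip(rng.normal(0.0, 1.0, n), -6.0, 6.0),
    }


@dataclass
class SimResult:
    """Everything one simulation produced, in memory."""

    config: SimConfig
    reference: dict[str, np.ndarray]
    trios: list[Trio]
    samples: list[str]
    records: list[SiteRecord]
    survey: list[SiteRecord]
    evidence: list[ReadEvidence]
    truth: TruthSet
    families: dict[str, FamilyGenotypes] = field(repr=False, default_factory=dict)


def simulate_observations(
    config: SimConfig,
    reference: dict[str, np.ndarray],
    families: dict[str, FamilyGenotypes],
    truth: TruthSet,
) -> tuple[list[SiteRecord], list[SiteRecord], list[ReadEvidence]]:
    """Turn true genotypes into noisy multi-sample site records.

    Depth is Poisson(``mean_depth``); the alternate-read count is binomial
    with a per-read error channel; genotypes are re-called by maximum
    likelihood so that miscalls arise from the data rather than by fiat.
    Injected artifact sites (child forced heterozygous, supported by
    parental reads in the fragment evidence) exercise the validation stage,
    and a fraction of them receive a failing site statistic.
    """
    rng = config.rng(4)
    samples = sample_order(config)
    sample_idx = {s: i for i, s in enumerate(samples)}
    n_samples = len(samples)
    eps_call = max(config.seq_error_rate, 1e-4)
    e = config.seq_error_rate
    p_alt_by_gt = np.array([e / 3.0, 0.5, 1.0 - 2.0 * e / 3.0])

    # --- assemble the union site table per chromosome -----------------------
    records: list[SiteRecord] = []
    evidence: list[ReadEvidence] = []
    frag_counter = itertools.count(1)

    # planted DNM lookup: (chrom, pos0) -> (ref, alt, carriers, origin)
    dnm_at: dict[tuple[str, int], PlantedDnm] = {
        (d.chrom, d.pos - 1): d for d in truth.planted_dnms
    }

    # injected artifact sites per offspring
    fp_sites: list[tuple[str, str, int, int, int, str]] = []
    # (child, chrom, pos0, refb, altb, kind)
    taken = {k for k in dnm_at}
    for fam in families.values():
        for chrom, fs in fam.sites.items():
            taken.update((chrom, int(p)) for p in fs.pos)
    for fam in families.values():
        for off in fam.offspring:
            for _ in range(rng.poisson(config.fp_per_offspring)):
                while True:
                    chrom = config.chromosomes[rng.integers(config.n_chromosomes)]
                    pos = int(rng.integers(reference[chrom].size))
                    if (chrom, pos) not in taken:
                        break
                taken.add((chrom, pos))
                refb = int(reference[chrom][pos])
                altb = int(_alt_bases(np.array([refb], dtype=np.uint8), rng)[0])
                kind = "parental_reads" if rng.random() < 0.5 else "low_support"
                fp_sites.append((off, chrom, pos, refb, altb, kind))
                truth.false_positive_sites.append(
                    (off, chrom, pos + 1, "ACGT"[refb], "ACGT"[altb])
                )

    fp_at: dict[tuple[str, int], tuple[str, int, int, str]] = {
        (chrom, pos): (off, refb, altb, kind)
        for off, chrom, pos, refb, altb, kind in fp_sites
    }

    for chrom in config.chromosomes:
        seq = reference[chrom]
        pos_set: set[int] = set()
        for fam in families.values():
            pos_set.update(int(p) for p in fam.sites[chrom].pos)
        pos_set.update(p for c, p in dnm_at if c == chrom)
        pos_set.update(p for c, p in fp_at if c == chrom)
        positions = np.array(sorted(pos_set), dtype=np.int64)
        n_sites = positions.size
        if n_sites == 0:
            continue
        pos_index = {int(p): i for i, p in enumerate(positions)}

        gt_true = np.zeros((n_sites, n_samples), dtype=np.uint8)
        ref_b = seq[positions].copy()
        alt_b = np.full(n_sites, 255, dtype=np.uint8)

        for fam in families.values():
            fs = fam.sites[chrom]
            if fs.pos.size == 0:
                continue
            rows = np.array([pos_index[int(p)] for p in fs.pos])
            alt_b[rows] = fs.alt
            fi = sample_idx[f"{fam.family}_father"]
            mi = sample_idx[f"{fam.family}_mother"]
            gt_true[rows, fi] = fs.f_gt
            gt_true[rows, mi] = fs.m_gt
            for k, off in enumerate(fam.offspring):
                oi = sample_idx[off]
                gt_true[rows, oi] = fs.child_pat[k] + fs.child_mat[k]
        for (c, p), d in dnm_at.items():
            if c != chrom:
                continue
            row = pos_index[p]
            alt_b[row] = _IDX[d.alt]
            for off in d.offspring:
                gt_true[row, sample_idx[off]] = 1
        for (c, p), (off, refb, altb, kind) in fp_at.items():
            if c != chrom:
                continue
            alt_b[pos_index[p]] = altb
        # sites that ended up with no alt (possible if a family table is
        # empty at this position after merging) get a random alt
        missing = alt_b == 255
        if missing.any():
            alt_b[missing] = _alt_bases(ref_b[missing], rng)

        # --- observation model, vectorised over the site x sample matrix ---
        dp = rng.poisson(config.mean_depth, size=(n_sites, n_samples))
        alt_reads = rng.binomial(dp, p_alt_by_gt[gt_true])
        gt_call, gq = _genotype_call(dp, alt_reads, eps_call)

        info = _passing_info(n_sites, rng)
        # artifact sites: force the child call het, optionally fail one stat
        for (c, p), (off, refb, altb, kind) in fp_at.items():
            if c != chrom:
                continue
            row, col = pos_index[p], sample_idx[off]
            d = max(int(dp[row, col]), 20)
            dp[row, col] = d
            alt_reads[row, col] = d // 2
            gt_call[row, col] = 1
            gq[row, col] = 60
            if rng.random() < config.info_fail_fraction:
                info["QD"][row] = 1.0

        for i in range(n_sites):
            calls = {}
            for j, s in enumerate(samples):
                g = int(gt_call[i, j])
                calls[s] = SampleCall(
                    gt=(0, 0) if g == 0 else ((0, 1) if g == 1 else (1, 1)),
                    dp=int(dp[i, j]),
                    ad=(int(dp[i, j] - alt_reads[i, j]), int(alt_reads[i, j])),
                    gq=int(gq[i, j]),
                )
            records.append(SiteRecord(
                chrom=chrom, pos=int(positions[i]) + 1,
                ref="ACGT"[int(ref_b[i])], alt="ACGT"[int(alt_b[i])],
                info={k: float(v[i]) for k, v in info.items()},
                calls=calls,
            ))

        # --- read evidence fragments ---------------------------------------
        def emit_fragment(sample: str, obs: list[tuple[str, int, str]]) -> None:
            noisy = []
            for oc, op, ob in obs:
                if e > 0 and rng.random() < e:
                    ob = "ACGT"[(_IDX[ob] + int(rng.integers(1, 4))) % 4]
                noisy.append((oc, op, ob))
            evidence.append(ReadEvidence(
                fragment_id=f"frag{next(frag_counter)}", sample=sample,
                observations=noisy,
            ))

        n_cover = max(2, int(round(config.mean_depth / 4)))
        for (c, p), d in dnm_at.items():
            if c != chrom:
                continue
            fam = families[d.family]
            fs = fam.sites[chrom]
            lo = np.searchsorted(fs.pos, p - config.fragment_length)
            hi = np.searchsorted(fs.pos, p + config.fragment_length)
            for off in d.offspring:
                k = fam.offspring.index(off)
                # unlinked fragments covering only the mutation site
                for _ in range(n_cover):
                    emit_fragment(off, [(chrom, d.pos, d.alt)])
                    emit_fragment(off, [(chrom, d.pos, d.ref)])
                # linked fragments tying the mutant allele to nearby sites
                for si in range(lo, hi):
                    spos = int(fs.pos[si]) + 1
                    site_ref = "ACGT"[int(fs.ref[si])]
                    site_alt = "ACGT"[int(fs.alt[si])]
                    if d.parent_of_origin == "paternal":
                        hap_with = fs.child_pat[k, si]
                        hap_without = fs.child_mat[k, si]
                    else:
                        hap_with = fs.child_mat[k, si]
                        hap_without = fs.child_pat[k, si]
                    with_base = site_alt if hap_with else site_ref
                    without_base = site_alt if hap_without else site_ref
                    for _ in range(3):
                        emit_fragment(off, [(chrom, d.pos, d.alt),
                                            (chrom, spos, with_base)])
                        emit_fragment(off, [(chrom, d.pos, d.ref),
                                            (chrom, spos, without_base)])
        for (c, p), (off, refb, altb, kind) in fp_at.items():
            if c != chrom:
                continue
            fam_id = off.split("_")[0]
            father = f"{fam_id}_father"
            pos1 = p + 1
            refs, alts = "ACGT"[refb], "ACGT"[altb]
            if kind == "parental_reads":
                for _ in range(n_cover):
                    emit_fragment(off, [(chrom, pos1, alts)])
                for _ in range(2):
                    emit_fragment(father, [(chrom, pos1, alts)])
            else:  # low child support
                emit_fragment(off, [(chrom, pos1, alts)])
                for _ in range(n_cover):
                    emit_fragment(off, [(chrom, pos1, refs)])

    # --- depth survey for callable-size estimation ---------------------------
    survey: list[SiteRecord] = []
    rng_s = config.rng(5)
    for chrom in config.chromosomes:
        seq = reference[chrom]
        positions = np.arange(0, seq.size, config.survey_stride)
        dp = rng_s.poisson(config.mean_depth, size=(positions.size, n_samples))
        poly: dict[int, dict[str, int]] = {}
        for fam in families.values():
            fs = fam.sites[chrom]
            for idx_site, p in enumerate(fs.pos):
                d = poly.setdefault(int(p), {})
                d[f"{fam.family}_father"] = int(fs.f_gt[idx_site])
                d[f"{fam.family}_mother"] = int(fs.m_gt[idx_site])
        for i, p in enumerate(positions):
            calls = {}
            overl = poly.get(int(p), {})
            for j, s in enumerate(samples):
                g = overl.get(s, 0)
                calls[s] = SampleCall(
                    gt=(0, 0) if g == 0 else ((0, 1) if g == 1 else (1, 1)),
                    dp=int(dp[i, j]),
                )
            survey.append(SiteRecord(
                chrom=chrom, pos=int(p) + 1, ref="ACGT"[int(seq[p])],
                alt=None, calls=calls,
            ))
    return records, survey, evidence


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: reference, parents, truth, observations."""
    reference = generate_reference(config)
    families = generate_parents(config, reference)
    truth = plant_dnms(config, reference, families)
    records, survey, evidence = simulate_observations(
        config, reference, families, truth
    )
    return SimResult(
        config=config, reference=reference, trios=make_pedigree(config),
        samples=sample_order(config), records=records, survey=survey,
        evidence=evidence, truth=truth, families=families,
    )


# ---------------------------------------------------------------------------
# Output writing
# ---------------------------------------------------------------------------

def write_truth(truth: TruthSet, path: str | Path) -> None:
    rows = [
        (d.family, ",".join(d.offspring), d.chrom, d.pos, d.ref, d.alt,
         d.parent_of_origin, int(d.pre_pgc), int(d.cpg))
        for d in truth.planted_dnms
    ]
    pd.DataFrame(rows, columns=[
        "family", "offspring", "chrom", "pos", "ref", "alt",
        "parent_of_origin", "pre_pgc", "cpg",
    ]).to_csv(path, sep="\t", index=False)


def write_outputs(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write VCF, survey VCF, FASTA, pedigree, truth and evidence files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = {c: result.config.callable_length for c in result.config.chromosomes}
    paths = {
        "vcf": outdir / "cohort.vcf",
        "survey": outdir / "survey.vcf",
        "fasta": outdir / "reference.fa",
        "pedigree": outdir / "pedigree.tsv",
        "truth": outdir / "truth.tsv",
        "evidence": outdir / "evidence.tsv",
    }
    write_vcf(result.records, result.samples, paths["vcf"], contigs)
    write_vcf(result.survey, result.samples, paths["survey"], contigs)
    write_fasta(reference_to_str(result.reference), paths["fasta"])
    write_pedigree(result.trios, paths["pedigree"])
    write_truth(result.truth, paths["truth"])
    write_read_evidence(result.evidence, paths["evidence"])
    return paths


# ---------------------------------------------------------------------------
# Annotation and linkage-map fixtures
# ---------------------------------------------------------------------------

def generate_annotation(
    config: SimConfig,
    mean_gene_length: int = 6000,
    gene_spacing: int = 20000,
    n_exons: int = 4,
) -> list[Transcript]:
    """Deterministically tile simple protein-coding gene models.

    Genes alternate strand, carry ``n_exons`` exons with UTR in the first
    and last exon, and a CDS whose length is a multiple of three with GFF3
    phase chained across segments. Adequate substrate for feature and codon
    effect annotation; no alternative isoforms.
    """
    rng = config.rng(6)
    transcripts: list[Transcript] = []
    gid = itertools.count(1)
    for chrom in config.chromosomes:
        L = config.callable_length
        start = int(rng.integers(2000, 6000))
        while start + mean_gene_length + 2000 < L:
            glen = int(mean_gene_length * (0.7 + 0.6 * rng.random()))
            strand = "+" if rng.random() < 0.5 else "-"
            exon_len = glen // (2 * n_exons - 1)
            exons = []
            p = start
            for k in range(n_exons):
                exons.append((p, p + exon_len))
                p += 2 * exon_len
            end = exons[-1][1]
            utr5 = exon_len // 3
            utr3 = exon_len // 3
            cds_iv = []
            for k, (s, e2) in enumerate(exons):
                cs, ce = s, e2
                if k == 0:
                    cs = s + utr5
                if k == n_exons - 1:
                    ce = e2 - utr3
                if ce > cs:
                    cds_iv.append([cs, ce])
            total = sum(ce - cs for cs, ce in cds_iv)
            trim = total % 3
            if trim:
                if strand == "+":
                    cds_iv[-1][1] -= trim
                else:
                    cds_iv[0][0] += trim
            # GFF3 phase: bases to skip to reach the next codon start
            cds = []
            if strand == "+":
                done = 0
                for cs, ce in cds_iv:
                    cds.append((cs, ce, (3 - done % 3) % 3))
                    done += ce - cs
            else:
                done = 0
                for cs, ce in reversed(cds_iv):
                    cds.append((cs, ce, (3 - done % 3) % 3))
                    done += ce - cs
                cds.sort()
            transcripts.append(Transcript(
                tid=f"tx{next(gid)}", chrom=chrom, start=start, end=end,
                strand=strand, exons=exons, cds=cds,
            ))
            start = end + int(gene_spacing * (0.5 + rng.random()))
    return transcripts


def synthetic_linkage_map(
    chrom_lengths: dict[str, int],
    rate_cm_per_mb: float = 3.78,
    point_spacing: int = 250_000,
    rate_profile=None,
) -> pd.DataFrame:
    """Linkage map with a constant rate or a per-position rate profile.

    ``rate_profile(chrom, pos) -> cM/Mb`` overrides the constant; genetic
    positions accumulate piecewise linearly between points.
    """
    rows = []
    for chrom, L in chrom_lengths.items():
        points = list(range(0, L + 1, point_spacing))
        if points[-1] != L:
            points.append(L)
        cm = 0.0
        prev = 0
        for p in points:
            rate = rate_cm_per_mb if rate_profile is None else rate_profile(chrom, prev)
            cm += (p - prev) / 1e6 * rate
            rows.append((chrom, p, cm))
            prev = p
    return pd.DataFrame(rows, columns=["chrom", "physical_pos", "genetic_pos"])


def generate_repeats(
    config: SimConfig, fraction: float = 0.166, block: int = 5000
) -> list[tuple[str, int, int]]:
    """Deterministic repeat-region mask covering ~``fraction`` of each chromosome."""
    rng = config.rng(7)
    out = []
    for chrom in config.chromosomes:
        L = config.callable_length
        n_blocks = int(L * fraction / block)
        starts = np.sort(rng.choice(max(1, L // block), size=min(n_blocks, L // block),
                                    replace=False)) * block
        for s in starts:
            out.append((chrom, int(s), int(min(s + block, L))))
    return out


# ---------------------------------------------------------------------------
# Event-level cohort simulation (full callable size, no per-base genome)
# ---------------------------------------------------------------------------

@dataclass
class EventLevelCohort:
    """Per-offspring mutation counts through detection and curation."""

    true_counts: np.ndarray  # planted DNMs per offspring
    detected_counts: np.ndarray  # surviving the AB-style thinning
    candidate_counts: np.ndarray  # detected + injected artifacts
    curated_counts: np.ndarray  # after validation removed the artifacts
    fdr_observed: float
    callable_sizes: np.ndarray
    fnr: float


def simulate_event_level(
    n_offspring: int,
    callable_size: float,
    mu: float,
    fnr: float,
    fp_mean: float,
    rng: np.random.Generator,
    fp_caught_prob: float = 1.0,
) -> EventLevelCohort:
    """Simulate the detection funnel at the level of mutation counts.

    Per offspring: true DNMs ~ Poisson(2 * CS * mu); each is detected with
    probability (1 - fnr), modelling the allelic-balance filter loss; on top,
    Poisson(``fp_mean``) artifact candidates are injected and removed again
    by validation with probability ``fp_caught_prob``. The curated counts,
    callable sizes and the FNR are exactly the ingredients of the pooled
    zero-inflated rate estimator.
    """
    true_counts = rng.poisson(2.0 * callable_size * mu, size=n_offspring)
    detected = rng.binomial(true_counts, 1.0 - fnr)
    fps = rng.poisson(fp_mean, size=n_offspring)
    caught = rng.binomial(fps, fp_caught_prob)
    candidates = detected + fps
    curated = detected + fps - caught
    total_cand = candidates.sum()
    fdr = caught.sum() / total_cand if total_cand else 0.0
    return EventLevelCohort(
        true_counts=true_counts,
        detected_counts=detected,
        candidate_counts=candidates,
        curated_counts=curated,
        fdr_observed=float(fdr),
        callable_sizes=np.full(n_offspring, float(callable_size)),
        fnr=fnr,
    )
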