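"""Mutation spectrum, GC bias, CpG islands and genomic-feature annotation.

Unique DNMs are collapsed onto a pyrimidine/purine-reference strand
(A>* and C>*) giving six mutation classes, with C>T at CpG dinucleotides
split out as a seventh. Strong-to-weak (S>W: C:G -> A:T) bias is tested
against per-base mutational opportunity from the callable GC fraction.
CpG islands are detected with the Gardiner-Garden & Frommer criteria
(length >= 200 bp, GC >= 50%, observed/expected CpG >= 0.6) and classified
against gene models; coding DNMs are resolved to synonymous/missense via
the reference codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from intervaltree import IntervalTree
from scipy import stats

from .io import Transcript

log = logging.getLogger("triodnm")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

MUTATION_CLASSES = (
    "A>C", "A>T", "A>G", "C>A", "C>G", "C>T", "C>T_CpG",
)
TRANSITION_CLASSES = {"A>G", "C>T", "C>T_CpG"}


@dataclass
class MutationClassCounts:
    counts: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in MUTATION_CLASSES}
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def ts(self) -> int:
        return sum(v for k, v in self.counts.items() if k in TRANSITION_CLASSES)

    @property
    def tv(self) -> int:
        return self.total - self.ts

    def add(self, cls: str) -> None:
        self.counts[cls] += 1


def classify_mutation(
    ref: str, alt: str, context: str
) -> tuple[str, bool]:
    """Assign one of the seven spectrum classes; flags ambiguous context.

    ``context`` is the reference trinucleotide centred on the site. Purine
    references are reverse-complemented onto the pyrimidine strand, so the
    class label always reads A>* or C>*. A C>T whose strand-collapsed 3'
    neighbour is G (a CpG dinucleotide) lands in the CpG class; an N in the
    relevant neighbour suppresses the CpG inspection and sets the flag.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"need distinct single bases, got {ref}>{alt}")
    context = context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError("context must be the ref-centred trinucleotide")
    if ref in "GT":
        # collapse onto the A/C (pyrimidine-reference) strand
        context = "".join(COMPLEMENT[b] for b in reversed(context))
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    cls = f"{ref}>{alt}"
    ambiguous = False
    if cls == "C>T":
        three_prime = context[2]
        if three_prime == "N":
            ambiguous = True
        elif three_prime == "G":
            cls = "C>T_CpG"
    return cls, ambiguous


def build_spectrum(
    mutations: Sequence[tuple[str, str, str]]
) -> MutationClassCounts:
    """Spectrum counts from (ref, alt, trinucleotide context) records."""
    out = MutationClassCounts()
    for ref, alt, ctx in mutations:
        cls, _ = classify_mutation(ref, alt, ctx)
        out.add(cls)
    return out


def ts_tv_ratio(counts: MutationClassCounts) -> float:
    if counts.tv == 0:
        raise ZeroDivisionError("no transversions: Ts:Tv undefined")
    return counts.ts / counts.tv


# ---------------------------------------------------------------------------
# Chi-square goodness of fit (closed-form Pearson)
# ---------------------------------------------------------------------------

@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    observed: tuple[float, ...]
    expected: tuple[float, ...]


def chi_square_gof(
    observed: Sequence[float], expected_proportions: Sequence[float]
) -> ChiSquareResult:
    """Pearson goodness-of-fit: sum (O-E)^2 / E with df = k - 1."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.size < 2 or obs.size != props.size:
        raise ValueError("need >= 2 matching categories")
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("expected proportions must sum to 1")
    exp = props * obs.sum()
    if np.any(exp == 0):
        raise ValueError("zero expected count")
    statistic = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    return ChiSquareResult(
        statistic=statistic, df=df,
        p_value=float(stats.chi2.sf(statistic, df)),
        observed=tuple(obs), expected=tuple(exp),
    )


STRONG = set("CG")
WEAK = set("AT")


def sw_bias_test(
    mutations: Sequence[tuple[str, str]], callable_gc_fraction: float
) -> ChiSquareResult:
    """Strong-to-weak vs weak-to-strong bias against mutational opportunity.

    S>W (C/G ref to A/T alt) counts are expected in proportion to the
    callable GC fraction and W>S to the AT fraction; within-class changes
    (S>S, W>W) are excluded. df = 1.
    """
    sw = ws = 0
    for ref, alt in mutations:
        r_strong = ref.upper() in STRONG
        a_strong = alt.upper() in STRONG
        if r_strong and not a_strong:
            sw += 1
        elif not r_strong and a_strong:
            ws += 1
    return chi_square_gof(
        [sw, ws], [callable_gc_fraction, 1.0 - callable_gc_fraction]
    )


# ---------------------------------------------------------------------------
# CpG islands
# ---------------------------------------------------------------------------

@dataclass
class CpgIsland:
    chrom: str
    start: int  # 0-based half-open
    end: int
    gc_fraction: float
    obs_exp_cpg: float
    cgi_class: Optional[str] = None  # intergenic|intronic|exonic|TSS|TTS

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("island end must exceed start")


@dataclass
class CgiParams:
    min_length: int = 200
    min_gc: float = 0.5
    min_obs_exp: float = 0.6


def _interval_stats(
    cum_gc: np.ndarray, cum_c: np.ndarray, cum_g: np.ndarray,
    cum_cpg: np.ndarray, s: int, e: int
) -> tuple[float, float]:
    """(GC fraction, obs/exp CpG) of [s, e) from prefix sums."""
    n = e - s
    gc = (cum_gc[e] - cum_gc[s]) / n
    c = cum_c[e] - cum_c[s]
    g = cum_g[e] - cum_g[s]
    cpg = cum_cpg[e] - cum_cpg[s] if e - 1 > s else 0
    if c == 0 or g == 0:
        return gc, 0.0
    return gc, cpg * n / (c * g)


def _prefix_sums(seq: str):
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    is_c = arr == b"C"
    is_g = arr == b"G"
    cpg = np.zeros(arr.size, dtype=np.int64)
    if arr.size > 1:
        cpg[:-1] = (is_c[:-1] & is_g[1:]).astype(np.int64)
    z = np.zeros(1, dtype=np.int64)
    cum = lambda x: np.concatenate([z, np.cumsum(x, dtype=np.int64)])
    # cum_cpg[i] counts CpG dinucleotide starts in [0, i)
    return cum(is_c | is_g), cum(is_c), cum(is_g), cum(cpg)


def _max_satisfying_end(sums, s: int, lo: int, hi: int,
                        params: CgiParams) -> int:
    """Largest e in [lo, hi] such that [s, e) satisfies the criteria (-1 if none)."""
    cum_gc, cum_c, cum_g, cum_cpg = sums
    if lo > hi:
        return -1
    ends = np.arange(lo, hi + 1)
    n = ends - s
    gc = (cum_gc[ends] - cum_gc[s]) / n
    c = cum_c[ends] - cum_c[s]
    g = cum_g[ends] - cum_g[s]
    cpg = cum_cpg[ends] - cum_cpg[s]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((c > 0) & (g > 0), cpg * n / (c * g), 0.0)
    ok = (gc >= params.min_gc) & (oe >= params.min_obs_exp)
    idx = np.flatnonzero(ok)
    return int(ends[idx[-1]]) if idx.size else -1


def _maximal_islands_in_block(
    sums, offset: int, length: int, params: CgiParams
) -> list[tuple[int, int]]:
    """Maximal satisfying intervals within one candidate block.

    An interval can only be contained in one starting no later, so with
    E(s) = the largest satisfying end for start s, the maximal intervals
    are exactly the (s, E(s)) whose E(s) exceeds every earlier E(s').
    """
    out: list[tuple[int, int]] = []
    best_end = -1
    for s in range(offset, offset + length - params.min_length + 1):
        e = _max_satisfying_end(sums, s, s + params.min_length,
                                offset + length, params)
        if e > best_end:
            out.append((s, e))
            best_end = e
    return out


def _merge_to_islands(
    candidates: list[tuple[int, int]], sums, chrom: str
) -> list[CpgIsland]:
    """Union of overlapping maximal satisfying intervals, one island each.

    Near a threshold boundary the maximal intervals form an overlapping
    staircase; their union is the reported island, with GC and obs/exp
    recomputed on the merged span.
    """
    cum_gc, cum_c, cum_g, cum_cpg = sums
    merged: list[list[int]] = []
    for s, e in sorted(candidates):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        gc, oe = _interval_stats(cum_gc, cum_c, cum_g, cum_cpg, s, e)
        out.append(CpgIsland(chrom=chrom, start=s, end=e,
                             gc_fraction=gc, obs_exp_cpg=oe))
    return out


def detect_cpg_islands(
    seq: str, chrom: str = "chr", params: Optional[CgiParams] = None
) -> list[CpgIsland]:
    """CpG islands: merged maximal intervals meeting the island criteria.

    The scan seeds candidate blocks with fixed-length windows that pass
    both thresholds, pads and merges nearby blocks, resolves each block to
    its maximal satisfying subintervals by exhaustive search, and reports
    the union of overlapping maximal intervals. On island-bearing
    sequences with a GC-poor background this equals the quadratic
    all-substring search.
    """
    if params is None:
        params = CgiParams()
    n = len(seq)
    if n < params.min_length:
        return []
    sums = _prefix_sums(seq)
    cum_gc, cum_c, cum_g, cum_cpg = sums
    w = params.min_length
    # windows passing both criteria
    gc_w = (cum_gc[w:] - cum_gc[:-w]) / w
    c_w = cum_c[w:] - cum_c[:-w]
    g_w = cum_g[w:] - cum_g[:-w]
    cpg_w = cum_cpg[w:] - cum_cpg[:-w]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe_w = np.where((c_w > 0) & (g_w > 0), cpg_w * w / (c_w * g_w), 0.0)
    pass_start = np.flatnonzero((gc_w >= params.min_gc) & (oe_w >= params.min_obs_exp))
    if pass_start.size == 0:
        return []
    # merge passing windows into blocks, then pad and re-merge
    blocks: list[list[int]] = []
    for s in pass_start:
        e = int(s) + w
        if blocks and int(s) <= blocks[-1][1]:
            blocks[-1][1] = max(blocks[-1][1], e)
        else:
            blocks.append([int(s), e])
    padded = []
    for s, e in blocks:
        pad = min(2 * (e - s), 5000)
        padded.append([max(0, s - pad), min(n, e + pad)])
    merged = [padded[0]]
    for s, e in padded[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    candidates: list[tuple[int, int]] = []
    for s, e in merged:
        candidates.extend(_maximal_islands_in_block(sums, s, e - s, params))
    out = _merge_to_islands(candidates, sums, chrom)
    out.sort(key=lambda i: i.start)
    return out


def brute_force_cpg_islands(
    seq: str, chrom: str = "chr", params: Optional[CgiParams] = None
) -> list[CpgIsland]:
    """Quadratic all-substring oracle for island detection (<= a few kb)."""
    if params is None:
        params = CgiParams()
    n = len(seq)
    sums = _prefix_sums(seq)
    cum_gc, cum_c, cum_g, cum_cpg = sums
    # per start, the largest satisfying end, by plain enumeration
    best: dict[int, int] = {}
    for s in range(0, n - params.min_length + 1):
        for e in range(s + params.min_length, n + 1):
            gc, oe = _interval_stats(cum_gc, cum_c, cum_g, cum_cpg, s, e)
            if gc >= params.min_gc and oe >= params.min_obs_exp:
                best[s] = e
    maximal = []
    for s, e in sorted(best.items()):
        contained = any(
            s2 <= s and e <= e2 and (s2, e2) != (s, e)
            for s2, e2 in best.items()
        )
        if not contained:
            maximal.append((s, e))
    out = _merge_to_islands(maximal, sums, chrom)
    out.sort(key=lambda i: i.start)
    return out


# ---------------------------------------------------------------------------
# CGI and DNM annotation against gene models
# ---------------------------------------------------------------------------

class FeatureIndex:
    """Interval lookups over transcript models for one genome."""

    def __init__(self, transcripts: Sequence[Transcript],
                 tss_tts_window: int = 500):
        self.window = tss_tts_window
        self.transcripts = list(transcripts)
        self.gene_trees: dict[str, IntervalTree] = {}
        self.exon_trees: dict[str, IntervalTree] = {}
        self.cds_trees: dict[str, IntervalTree] = {}
        self.tss_trees: dict[str, IntervalTree] = {}
        self.tts_trees: dict[str, IntervalTree] = {}
        for t in transcripts:
            self.gene_trees.setdefault(t.chrom, IntervalTree()).addi(
                t.start, t.end, t
            )
            for s, e in t.exons:
                self.exon_trees.setdefault(t.chrom, IntervalTree()).addi(s, e, t)
            for s, e, ph in t.cds:
                self.cds_trees.setdefault(t.chrom, IntervalTree()).addi(
                    s, e, (t, ph)
                )
            self.tss_trees.setdefault(t.chrom, IntervalTree()).addi(
                max(0, t.tss - self.window), t.tss + self.window + 1, t
            )
            self.tts_trees.setdefault(t.chrom, IntervalTree()).addi(
                max(0, t.tts - self.window), t.tts + self.window + 1, t
            )

    def _hits(self, trees, chrom, start, end):
        tree = trees.get(chrom)
        return tree.overlap(start, end) if tree is not None else set()


def classify_cgi(
    island: CpgIsland, index: FeatureIndex
) -> str:
    """Island class by location: TSS > TTS > exonic > intronic > intergenic."""
    s, e = island.start, island.end
    if index._hits(index.tss_trees, island.chrom, s, e):
        return "TSS"
    if index._hits(index.tts_trees, island.chrom, s, e):
        return "TTS"
    if index._hits(index.exon_trees, island.chrom, s, e):
        return "exonic"
    if index._hits(index.gene_trees, island.chrom, s, e):
        return "intronic"
    return "intergenic"


@dataclass
class FeatureAnnotation:
    feature: str  # exonic_UTR | exonic_synonymous | exonic_missense |
    # exonic_unresolved | intronic | intergenic
    repetitive: bool = False
    transcript: Optional[str] = None


def _coding_effect(
    transcript: Transcript, pos0: int, alt: str, reference: dict[str, str]
) -> str:
    """Synonymous/missense by translating the reference vs mutant codon."""
    cds = sorted(transcript.cds)
    seq = reference[transcript.chrom]
    coding = "".join(seq[s:e] for s, e, _ in cds)
    acc = 0
    cds_offset = None
    for s, e, _ in cds:
        if s <= pos0 < e:
            cds_offset = acc + (pos0 - s)
        acc += e - s
    if cds_offset is None:
        raise ValueError("position not in CDS")
    first_phase = cds[0][2] if transcript.strand == "+" else cds[-1][2]
    if transcript.strand == "+":
        idx = cds_offset - first_phase
        if idx < 0:
            return "exonic_unresolved"
        coding_eff = coding[first_phase:]
        mut = coding_eff[:idx] + alt + coding_eff[idx + 1:]
    else:
        rc = str(Seq(coding).reverse_complement())
        idx = (len(coding) - 1 - cds_offset) - first_phase
        if idx < 0:
            return "exonic_unresolved"
        coding_eff = rc[first_phase:]
        mut = coding_eff[:idx] + COMPLEMENT[alt] + coding_eff[idx + 1:]
    codon_i = idx // 3
    ref_codon = coding_eff[codon_i * 3: codon_i * 3 + 3]
    alt_codon = mut[codon_i * 3: codon_i * 3 + 3]
    if len(ref_codon) < 3:
        return "exonic_unresolved"
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return "exonic_synonymous" if ref_aa == alt_aa else "exonic_missense"


def annotate_feature(
    chrom: str, pos: int, alt: str,
    index: FeatureIndex,
    reference: dict[str, str],
    repeats: Optional[dict[str, IntervalTree]] = None,
) -> FeatureAnnotation:
    """Feature class of a DNM (1-based position) with repetitive-region flag.

    Inside a coding segment the reference and mutant codons are translated
    (strand- and phase-aware); exonic but non-coding positions are UTR when
    the transcript codes at all, and transcripts without CDS records are
    treated as non-coding (their exons do not yield UTR calls). Outside
    exons but inside a gene is intronic; elsewhere intergenic.
    """
    pos0 = pos - 1
    repetitive = False
    if repeats is not None:
        tree = repeats.get(chrom)
        repetitive = bool(tree is not None and tree.overlap(pos0, pos0 + 1))

    cds_hits = index._hits(index.cds_trees, chrom, pos0, pos0 + 1)
    if cds_hits:
        transcript = sorted(cds_hits, key=lambda h: h.data[0].tid)[0].data[0]
        try:
            effect = _coding_effect(transcript, pos0, alt, reference)
        except Exception as exc:
            log.warning("codon effect failed for %s at %s:%d: %s",
                        transcript.tid, chrom, pos, exc)
            effect = "exonic_unresolved"
        return FeatureAnnotation(feature=effect, repetitive=repetitive,
                                 transcript=transcript.tid)
    exon_hits = [h for h in index._hits(index.exon_trees, chrom, pos0, pos0 + 1)
                 if h.data.coding]
    if exon_hits:
        t = sorted(exon_hits, key=lambda h: h.data.tid)[0].data
        return FeatureAnnotation(feature="exonic_UTR", repetitive=repetitive,
                                 transcript=t.tid)
    gene_hits = [h for h in index._hits(index.gene_trees, chrom, pos0, pos0 + 1)
                 if h.data.coding]
    if gene_hits:
        t = sorted(gene_hits, key=lambda h: h.data.tid)[0].data
        return FeatureAnnotation(feature="intronic", repetitive=repetitive,
                                 transcript=t.tid)
    return FeatureAnnotation(feature="intergenic", repetitive=repetitive)


def feature_randomness_test(
    feature_counts: Sequence[float], callable_bp_per_feature: Sequence[float]
) -> ChiSquareResult:
    """DNM counts vs expectation proportional to callable bp per feature."""
    bp = np.asarray(callable_bp_per_feature, dtype=float)
    if np.any(bp <= 0):
        raise ValueError("callable bp per feature must be positive")
    return chi_square_gof(feature_counts, bp / bp.sum())


def repeats_to_trees(
    intervals: Sequence[tuple[str, int, int]]
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in intervals:
        trees.setdefault(chrom, IntervalTree()).addi(s, e)
    return trees


def trinucleotide_context(reference: dict[str, str], chrom: str, pos: int) -> str:
    """Ref-centred trinucleotide at a 1-based position ('N'-padded at ends)."""
    seq = reference[chrom]
    i = pos - 1
    left = seq[i - 1] if i >= 1 else "N"
    right = seq[i + 1] if i + 1 < len(seq) else "N"
    return f"{left}{seq[i]}{right}"
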