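"""Sliding-window mutation landscape and its genomic correlates.

Windows (5 Mb, advancing 1 Mb by default) carry the unique-DNM count, the
local recombination rate interpolated from a linkage map
(r = genetic distance / physical distance, cM/Mb), CpG dinucleotide
density, protein-coding gene density and callable bp. On top sit Pearson
correlations, single-factor Poisson regressions with a log-callable offset,
and a two-stage mediation path analysis of
CpG content -> recombination -> DNM count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import Transcript

log = logging.getLogger("triodnm")

WINDOW_SIZE = 5_000_000
WINDOW_STEP = 1_000_000


def interpolate_genetic_position(
    map_df: pd.DataFrame, chrom: str, pos: float | np.ndarray
) -> np.ndarray:
    """cM at physical position(s) by piecewise-linear interpolation.

    Positions outside the mapped range clamp to the terminal genetic
    positions — no extrapolation beyond the map.
    """
    sub = map_df[map_df["chrom"] == chrom]
    if len(sub) < 2:
        raise ValueError(f"chromosome {chrom!r} has fewer than 2 map points")
    return np.interp(
        np.asarray(pos, dtype=float),
        sub["physical_pos"].to_numpy(dtype=float),
        sub["genetic_pos"].to_numpy(dtype=float),
    )


def window_recombination(
    map_df: pd.DataFrame, chrom: str, start: int, end: int
) -> float:
    """Recombination rate of [start, end): delta cM / delta Mb."""
    if end <= start:
        raise ValueError("zero-length window")
    cm = interpolate_genetic_position(map_df, chrom, [start, end])
    return float((cm[1] - cm[0]) / ((end - start) / 1e6))


def _cpg_positions(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    return np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))


def build_windows(
    chrom_lengths: dict[str, int],
    dnms: Sequence[tuple[str, int]],
    reference: Optional[dict[str, str]] = None,
    transcripts: Optional[Sequence[Transcript]] = None,
    map_df: Optional[pd.DataFrame] = None,
    callable_fraction: float | dict[str, float] = 1.0,
    window_size: int = WINDOW_SIZE,
    window_step: int = WINDOW_STEP,
    keep_terminal: bool = True,
) -> pd.DataFrame:
    """Sliding-window table of DNM counts and genomic covariates.

    DNMs are unique events at 1-based positions and are counted in every
    overlapping window. Genes are assigned to windows by start coordinate
    so non-overlapping windows partition them. Terminal windows shorter
    than the window size are retained with their true length and flagged.
    """
    dnm_by_chrom: dict[str, np.ndarray] = {}
    for chrom in chrom_lengths:
        pos = np.array(sorted(p - 1 for c, p in dnms if c == chrom), dtype=np.int64)
        dnm_by_chrom[chrom] = pos
    gene_starts: dict[str, np.ndarray] = {}
    if transcripts is not None:
        for chrom in chrom_lengths:
            starts = sorted(
                t.start for t in transcripts if t.chrom == chrom and t.coding
            )
            gene_starts[chrom] = np.array(starts, dtype=np.int64)
    rows = []
    for chrom, L in chrom_lengths.items():
        cpg = _cpg_positions(reference[chrom]) if reference is not None else None
        starts = list(range(0, max(L - window_size, 0) + 1, window_step))
        # terminal truncated windows continue past the last full window
        if keep_terminal:
            s = starts[-1] + window_step if starts else 0
            while s < L:
                starts.append(s)
                s += window_step
        if not starts:
            starts = [0]
        for s in starts:
            e = min(s + window_size, L)
            n = e - s
            dn = dnm_by_chrom[chrom]
            count = int(np.searchsorted(dn, e) - np.searchsorted(dn, s))
            rec = (window_recombination(map_df, chrom, s, e)
                   if map_df is not None else np.nan)
            if cpg is not None:
                ncpg = int(np.searchsorted(cpg, e) - np.searchsorted(cpg, s))
                cpg_density = ncpg / n
            else:
                cpg_density = np.nan
            if chrom in gene_starts:
                gs = gene_starts[chrom]
                ngene = int(np.searchsorted(gs, e) - np.searchsorted(gs, s))
                gene_density = ngene / n
            else:
                gene_density = np.nan
            frac = (callable_fraction.get(chrom, 1.0)
                    if isinstance(callable_fraction, dict) else callable_fraction)
            rows.append((chrom, s, e, n, count, rec, cpg_density, gene_density,
                         frac * n, n < window_size))
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "length", "dnm_count", "rec_rate",
        "cpg_density", "gene_density", "callable_bp", "truncated",
    ])


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    overlapping_windows: bool  # autocorrelation caveat
    status: str = "ok"  # ok | undefined


def correlate_windows(
    table: pd.DataFrame, x: str, y: str
) -> CorrelationResult:
    """Pearson product-moment correlation between two window statistics.

    Overlapping sliding windows are serially correlated; the result flags
    that caveat rather than correcting for it.
    """
    sub = table[[x, y]].dropna()
    if len(sub) < 3:
        raise ValueError("need >= 3 windows with finite values")
    xs, ys = sub[x].to_numpy(), sub[y].to_numpy()
    if np.std(xs) == 0 or np.std(ys) == 0:
        return CorrelationResult(r=float("nan"), p_value=float("nan"),
                                 n=len(sub), overlapping_windows=True,
                                 status="undefined")
    r, p = stats.pearsonr(xs, ys)
    overlapping = bool((table["end"] - table["start"]).max()
                       > (table.groupby("chrom")["start"].diff().dropna().min()
                          or np.inf))
    return CorrelationResult(r=float(r), p_value=float(p), n=len(sub),
                             overlapping_windows=overlapping)


@dataclass
class PoissonFit:
    factor: str
    coefficient: float
    std_error: float
    p_value: float
    converged: bool
    status: str = "ok"


def poisson_window_regression(
    table: pd.DataFrame, factor: str
) -> PoissonFit:
    """Poisson GLM: dnm_count ~ factor, offset log(callable_bp).

    One factor per model; windows with zero callable bp or missing factor
    values are dropped.
    """
    sub = table[["dnm_count", factor, "callable_bp"]].dropna()
    sub = sub[sub["callable_bp"] > 0]
    if len(sub) < 10:
        raise ValueError("need >= 10 usable windows")
    if float(sub[factor].std(ddof=0)) == 0.0:
        # a constant covariate is indistinguishable from the intercept
        return PoissonFit(factor=factor, coefficient=0.0, std_error=float("nan"),
                          p_value=1.0, converged=True, status="constant_factor")
    X = sm.add_constant(sub[[factor]].to_numpy())
    try:
        fit = sm.GLM(
            sub["dnm_count"].to_numpy(), X,
            family=sm.families.Poisson(),
            offset=np.log(sub["callable_bp"].to_numpy()),
        ).fit()
        converged = bool(fit.converged)
    except Exception as exc:
        log.warning("Poisson regression on %s failed: %s", factor, exc)
        return PoissonFit(factor=factor, coefficient=float("nan"),
                          std_error=float("nan"), p_value=float("nan"),
                          converged=False, status="failed")
    return PoissonFit(
        factor=factor, coefficient=float(fit.params[1]),
        std_error=float(fit.bse[1]), p_value=float(fit.pvalues[1]),
        converged=converged, status="ok" if converged else "not_converged",
    )


@dataclass
class PathAnalysis:
    """Two-stage mediation of CpG content on DNM count via recombination."""

    cpg_to_rec: float
    cpg_to_rec_p: float
    rec_to_dnm: float
    rec_to_dnm_p: float
    cpg_direct: float
    cpg_direct_p: float
    indirect_effect: float
    sobel_p: float
    total_effect: float
    collinearity_warning: bool


def mediation_path(
    table: pd.DataFrame,
    exposure: str = "cpg_density",
    mediator: str = "rec_rate",
    outcome: str = "dnm_count",
    condition_threshold: float = 1e6,
) -> PathAnalysis:
    """Standardized two-equation path model with a Sobel test.

    Stage (i): mediator ~ exposure; stage (ii): outcome ~ mediator +
    exposure. All variables are z-scored, so coefficients are path
    coefficients; the indirect effect is the product of the stage-(i)
    slope and the mediator's stage-(ii) slope. Severe collinearity is
    reported as a warning, never as a failure.
    """
    sub = table[[exposure, mediator, outcome]].dropna()
    if len(sub) < 10:
        raise ValueError("need >= 10 usable windows")
    z = (sub - sub.mean()) / sub.std(ddof=0)
    xz = z[exposure].to_numpy()
    mz = z[mediator].to_numpy()
    yz = z[outcome].to_numpy()
    m1 = sm.OLS(mz, sm.add_constant(xz)).fit()
    X2 = sm.add_constant(np.column_stack([mz, xz]))
    m2 = sm.OLS(yz, X2).fit()
    a, se_a = m1.params[1], m1.bse[1]
    b, se_b = m2.params[1], m2.bse[1]
    direct, direct_p = m2.params[2], m2.pvalues[2]
    indirect = a * b
    sobel_se = np.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
    sobel_p = 2.0 * stats.norm.sf(abs(indirect) / sobel_se) if sobel_se > 0 else 1.0
    cond = np.linalg.cond(X2)
    if cond > condition_threshold:
        log.warning("design matrix condition number %.3g: collinearity", cond)
    total = sm.OLS(yz, sm.add_constant(xz)).fit().params[1]
    return PathAnalysis(
        cpg_to_rec=float(a), cpg_to_rec_p=float(m1.pvalues[1]),
        rec_to_dnm=float(b), rec_to_dnm_p=float(m2.pvalues[1]),
        cpg_direct=float(direct), cpg_direct_p=float(direct_p),
        indirect_effect=float(indirect), sobel_p=float(sobel_p),
        total_effect=float(total),
        collinearity_warning=bool(cond > condition_threshold),
    )
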