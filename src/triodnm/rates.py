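"""Per-generation mutation-rate estimators with confidence intervals.

The per-trio estimator is

    mu = n_candidates * (1 - FDR) / (2 * CS * (1 - FNR))

and the pooled ("zero-inflated", because offspring with zero curated DNMs
stay in the denominator) estimator is

    mu = sum(curated counts) / (2 * sum(CS) * (1 - mean FNR)).

CS is the callable genome size of the offspring, FDR the validation-stage
false discovery rate and FNR the allelic-balance false negative rate. The
diploid factor 2 converts callable bases to callable base-generations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class RateEstimate:
    mu: float
    ci_low: float
    ci_high: float
    method: str  # per_trio_mean | pooled_zero_inflated | stratified
    n_dnm: float
    sum_cs: float
    fdr: float
    fnr: float
    generation_time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not (0 <= self.fdr < 1 and 0 <= self.fnr < 1):
            raise ValueError("fdr and fnr must lie in [0, 1)")


class UndefinedRateError(ValueError):
    pass


def per_trio_rate(
    n_candidates: float, fdr: float, cs: float, fnr: float
) -> RateEstimate:
    """Single-offspring rate: n * (1-FDR) / (2 * CS * (1-FNR))."""
    if cs <= 0:
        raise UndefinedRateError("callable size must be positive")
    if fnr >= 1:
        raise UndefinedRateError("FNR = 1 leaves no detectable heterozygotes")
    mu = n_candidates * (1.0 - fdr) / (2.0 * cs * (1.0 - fnr))
    return RateEstimate(mu=mu, ci_low=mu, ci_high=mu, method="per_trio_mean",
                        n_dnm=n_candidates, sum_cs=cs, fdr=fdr, fnr=fnr)


def pooled_rate(
    curated_counts: Sequence[float],
    callable_sizes: Sequence[float],
    mean_fnr: float,
) -> RateEstimate:
    """Pooled zero-inflated rate over all offspring.

    The numerator sums curated (post-validation) per-offspring counts —
    zeros included — so no FDR term remains; the denominator is twice the
    summed callable size, corrected for the mean FNR.
    """
    counts = np.asarray(curated_counts, dtype=float)
    cs = np.asarray(callable_sizes, dtype=float)
    if counts.shape != cs.shape:
        raise ValueError("counts and callable sizes must align")
    if not np.any(cs > 0):
        raise UndefinedRateError("all callable sizes are zero")
    if mean_fnr >= 1:
        raise UndefinedRateError("mean FNR = 1")
    mu = counts.sum() / (2.0 * cs.sum() * (1.0 - mean_fnr))
    return RateEstimate(
        mu=float(mu), ci_low=float(mu), ci_high=float(mu),
        method="pooled_zero_inflated", n_dnm=float(counts.sum()),
        sum_cs=float(cs.sum()), fdr=0.0, fnr=mean_fnr,
    )


def per_offspring_rates(
    counts: Sequence[float],
    callable_sizes: Sequence[float],
    fdr: float,
    fnrs: Sequence[float] | float,
) -> np.ndarray:
    """Vector of per-offspring rates under the single-trio formula."""
    counts = np.asarray(counts, dtype=float)
    cs = np.asarray(callable_sizes, dtype=float)
    fnr = np.broadcast_to(np.asarray(fnrs, dtype=float), counts.shape)
    return counts * (1.0 - fdr) / (2.0 * cs * (1.0 - fnr))


def rate_confidence_interval(
    per_offspring: Optional[Sequence[float]] = None,
    method: str = "normal_se",
    pooled_count: Optional[float] = None,
    pooled_denominator: Optional[float] = None,
    n_bootstrap: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """95% (by default) CI for the cohort mutation rate.

    ``normal_se``: mean +/- z * SE over per-offspring rates (needs >= 2
    offspring). ``bootstrap``: seeded nonparametric bootstrap over
    offspring. ``poisson``: exact Poisson limits on the pooled numerator,
    scaled by the pooled denominator (2 * sum(CS) * (1 - mean FNR)).
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    if method in ("normal_se", "bootstrap"):
        if per_offspring is None:
            raise ValueError(f"{method} CI needs per-offspring rates")
        x = np.asarray(per_offspring, dtype=float)
        if method == "normal_se":
            if x.size < 2:
                raise ValueError(
                    "normal-SE CI needs >= 2 offspring; use method='poisson'"
                )
            se = x.std(ddof=1) / np.sqrt(x.size)
            m = x.mean()
            return float(m - z * se), float(m + z * se)
        rng = np.random.default_rng(seed)
        means = rng.choice(x, size=(n_bootstrap, x.size), replace=True).mean(axis=1)
        lo, hi = np.quantile(means, [0.5 - level / 2.0, 0.5 + level / 2.0])
        return float(lo), float(hi)
    if method == "poisson":
        if pooled_count is None or pooled_denominator is None or pooled_denominator <= 0:
            raise ValueError("poisson CI needs pooled_count and pooled_denominator")
        lo, hi = poisson_count_interval(pooled_count, level)
        return lo / pooled_denominator, hi / pooled_denominator
    raise ValueError(f"unknown CI method {method!r}")


def poisson_count_interval(n: float, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson confidence limits for an observed count."""
    a = 1.0 - level
    lo = stats.chi2.ppf(a / 2.0, 2 * n) / 2.0 if n > 0 else 0.0
    hi = stats.chi2.ppf(1.0 - a / 2.0, 2 * (n + 1)) / 2.0
    return float(lo), float(hi)


def yearly_rate(estimate: RateEstimate, generation_time: float) -> float:
    """Per-bp per-year rate: mu divided by the generation time in years."""
    if generation_time <= 0:
        raise ValueError("generation time must be positive")
    return estimate.mu / generation_time


def stratified_rate(
    dnms: Sequence[tuple[str, int]],
    mask: dict[str, Sequence[tuple[int, int]]],
    masked_callable_sizes: Sequence[float],
    mean_fnr: float,
    counts_per_dnm: Optional[Sequence[int]] = None,
) -> RateEstimate:
    """Pooled rate restricted to a genomic mask.

    ``dnms`` are unique events as (chrom, 1-based pos); ``mask`` maps
    chromosome to 0-based half-open intervals; ``masked_callable_sizes``
    are per-offspring callable bp inside the mask, computed with the same
    callable rule. ``counts_per_dnm`` (default 1 each) lets shared events
    enter once per carrier offspring, matching the pooled numerator
    convention.
    """
    if not mask or all(len(v) == 0 for v in mask.values()):
        raise ValueError("empty region mask")
    if counts_per_dnm is None:
        counts_per_dnm = [1] * len(dnms)
    inside = 0.0
    for (chrom, pos), k in zip(dnms, counts_per_dnm):
        for s, e in mask.get(chrom, ()):
            if s <= pos - 1 < e:
                inside += k
                break
    est = pooled_rate([inside], [float(np.sum(masked_callable_sizes))], mean_fnr)
    est.method = "stratified"
    return est


def cohort_rates(
    curated_counts: Sequence[float],
    callable_sizes: Sequence[float],
    fdr: float,
    fnrs: Sequence[float] | float,
    ci_method: str = "normal_se",
    seed: int = 0,
) -> dict[str, RateEstimate]:
    """Per-trio-mean and pooled estimates with a CI on each.

    The per-trio-mean estimate averages single-offspring rates (curated
    counts, so FDR enters as 0 there); the pooled estimate follows the
    zero-inflated formula. The CI from ``ci_method`` is attached to both.
    """
    fnr_arr = np.broadcast_to(np.asarray(fnrs, dtype=float),
                              np.asarray(curated_counts, dtype=float).shape)
    rates = per_offspring_rates(curated_counts, callable_sizes, fdr, fnr_arr)
    mean_fnr = float(fnr_arr.mean())
    pooled = pooled_rate(curated_counts, callable_sizes, mean_fnr)
    denom = 2.0 * float(np.sum(callable_sizes)) * (1.0 - mean_fnr)
    if ci_method == "poisson":
        lo, hi = rate_confidence_interval(
            method="poisson", pooled_count=pooled.n_dnm, pooled_denominator=denom
        )
    else:
        lo, hi = rate_confidence_interval(rates, method=ci_method, seed=seed)
    per_trio = RateEstimate(
        mu=float(rates.mean()), ci_low=lo, ci_high=hi, method="per_trio_mean",
        n_dnm=float(np.sum(curated_counts)), sum_cs=float(np.sum(callable_sizes)),
        fdr=fdr, fnr=mean_fnr,
    )
    pooled.ci_low, pooled.ci_high = lo, hi
    return {"per_trio_mean": per_trio, "pooled_zero_inflated": pooled}
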