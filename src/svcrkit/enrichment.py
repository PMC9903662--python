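"""Frequency-matched resampling enrichment and detection-power arithmetic.

Whether a set of genes (or variants) carries more phenotype associations
than expected cannot be read off directly, because association power is
driven by cumulative allele frequency (CAF). The matched-resampling engine
therefore bins units by CAF into equal-width bins (default width 0.01) and
draws, for each target unit, a background unit from the same bin — with
replacement, ``n_sets`` times — yielding a null distribution of the
proportion of units with at least one association and of the mean
association count. The same engine serves gene sets, deleteriousness bins
of missense variants, and clinical-pathogenicity classes: each is just a
(target, background, frequency key) instance.

Power side: a purely additive biallelic variant with allele frequency p and
allelic effect a explains variance 2 p q a^2 (q = 1 - p); the association
chi-square test has noncentrality n times the variance explained, so the
minimum detectable variance-explained at a given level and power follows by
inverting the noncentral chi-square tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

CAF_BIN_WIDTH = 0.01
N_RESAMPLES = 1000


def cumulative_allele_frequency(member_afs: Sequence[float]) -> float:
    """Sum of a group's member allele frequencies (uncapped); empty -> 0."""
    afs = list(member_afs)
    if any(not 0.0 < af <= 1.0 for af in afs):
        raise ValueError("member allele frequencies must be in (0, 1]")
    return float(sum(afs))


def caf_bin(caf: float, width: float = CAF_BIN_WIDTH) -> int:
    """Index of the half-open bin [k*width, (k+1)*width) containing ``caf``."""
    return int(np.floor(caf / width))


@dataclass
class EnrichmentResult:
    n_target: int
    observed_proportion: float
    observed_mean: float
    null_proportions: np.ndarray
    null_means: np.ndarray
    empirical_p: float
    empirical_p_mean: float
    fisher_p: float | None = None
    odds_ratio: float | None = None
    or_flag: str | None = None
    target_ci: tuple[float, float] | None = None
    background_ci: tuple[float, float] | None = None


def caf_matched_null(
    target: pd.DataFrame,
    background: pd.DataFrame,
    bin_width: float = CAF_BIN_WIDTH,
    n_sets: int = N_RESAMPLES,
    seed: int = 0,
    top_bin_edge: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Null distributions from CAF-matched resampling of the background.

    ``target`` and ``background`` need columns ``caf`` and ``n_significant``
    (association count at the significance threshold). Each resample draws,
    for every target unit, one background unit from the same CAF bin with
    replacement, and records the proportion of drawn units with at least one
    association and their mean association count. ``top_bin_edge``
    optionally collapses all CAFs at or above it into one open-ended bin.
    Raises if a target bin has no background unit, naming the bin.
    """

    def bins_of(caf_values: np.ndarray) -> np.ndarray:
        b = np.floor(np.asarray(caf_values, dtype=float) / bin_width).astype(int)
        if top_bin_edge is not None:
            cap = int(np.floor(top_bin_edge / bin_width))
            b = np.minimum(b, cap)
        return b

    t_bins = bins_of(target["caf"].to_numpy())
    b_bins = bins_of(background["caf"].to_numpy())
    b_sig = background["n_significant"].to_numpy(dtype=float)

    by_bin: dict[int, np.ndarray] = {
        b: np.nonzero(b_bins == b)[0] for b in np.unique(t_bins)
    }
    for b in np.unique(t_bins):
        if by_bin[b].size == 0:
            lo, hi = b * bin_width, (b + 1) * bin_width
            raise ValueError(
                f"no background units in CAF bin [{lo:g}, {hi:g}) "
                f"required by the target set"
            )

    rng = np.random.default_rng(seed)
    n_t = len(t_bins)
    drawn = np.empty((n_sets, n_t))
    for j, b in enumerate(t_bins):
        pool = b_sig[by_bin[b]]
        drawn[:, j] = pool[rng.integers(0, len(pool), size=n_sets)]
    return (drawn >= 1).mean(axis=1), drawn.mean(axis=1)


def enrichment_test(
    target: pd.DataFrame,
    null_proportions: np.ndarray,
    null_means: np.ndarray,
    background_hits: int | None = None,
    background_total: int | None = None,
) -> EnrichmentResult:
    """Compare the target set's association rate with its matched null.

    The empirical p is the smoothed one-sided exceedance (r + 1)/(n + 1) of
    the null proportions over the observed proportion; ``empirical_p_mean``
    is the same exceedance on the mean association count, whose near-
    continuous null makes it the better-calibrated statistic (the
    proportion takes only n_target + 1 values, so its p is lumpy by
    construction). If background counts
    are supplied, a 2x2 Fisher exact test (target vs background, >= 1
    association vs none) with the sample (cross-product) odds ratio and
    Wilson 95% CIs on both proportions is added; a zero margin leaves the
    odds ratio undefined with a flag.
    """
    n_target = len(target)
    hits = int((target["n_significant"] >= 1).sum())
    obs_prop = hits / n_target
    obs_mean = float(target["n_significant"].mean())
    r = int((null_proportions >= obs_prop).sum())
    emp_p = (r + 1) / (len(null_proportions) + 1)
    r_mean = int((null_means >= obs_mean).sum())
    emp_p_mean = (r_mean + 1) / (len(null_means) + 1)

    result = EnrichmentResult(
        n_target=n_target,
        observed_proportion=obs_prop,
        observed_mean=obs_mean,
        null_proportions=np.asarray(null_proportions),
        null_means=np.asarray(null_means),
        empirical_p=emp_p,
        empirical_p_mean=emp_p_mean,
    )
    if background_hits is not None and background_total is not None:
        a, b = hits, n_target - hits
        c, d = background_hits, background_total - background_hits
        table = np.array([[a, b], [c, d]])
        _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
        result.fisher_p = float(fisher_p)
        if min(a + b, c + d, a + c, b + d) == 0 or b == 0 or c == 0:
            if a * d == 0:
                result.or_flag = "zero_margin"
            else:
                result.odds_ratio = np.inf
                result.or_flag = "infinite"
        else:
            result.odds_ratio = (a * d) / (b * c)
        result.target_ci = tuple(
            float(x) for x in proportion_confint(a, n_target, method="wilson")
        )
        result.background_ci = tuple(
            float(x)
            for x in proportion_confint(background_hits, background_total, method="wilson")
        )
    return result


# ---------------------------------------------------------------------------
# power arithmetic


def variance_explained(p: float, a: float) -> float:
    """Variance explained by a purely additive biallelic variant: 2 p q a^2."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must be in (0, 1), got {p}")
    return 2.0 * p * (1.0 - p) * a**2


def chi2_power(v: float, n: int, alpha: float) -> float:
    """Power of a 1-df chi-square test with noncentrality n * v at level alpha."""
    crit = stats.chi2.isf(alpha, 1)
    return float(stats.ncx2.sf(crit, 1, n * v))


def min_detectable_varexp(
    n: int, alpha: float, power: float, tol: float = 1e-12
) -> float:
    """Smallest variance-explained detectable at the given level and power.

    Solved by bisection on v in the monotone power function; halving the
    sample size exactly doubles the result (the noncentrality n * v is the
    only way n enters).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must be in (0, 1)")
    lo, hi = 0.0, 1.0
    while chi2_power(hi, n, alpha) < power:
        hi *= 2.0
    while hi - lo > tol * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if chi2_power(mid, n, alpha) >= power:
            hi = mid
        else:
            lo = mid
    return hi
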