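"""Sample-level quality control.

Covers the interval screen (fraction of samples at minimum coverage over
padded capture intervals), sex-karyotype imputation from normalized X/Y
ploidy estimates, the post-interval sample hard filters (karyotype, call
rate, mean coverage), stratified median-absolute-deviation outlier flagging,
and greedy maximal-independent-set pruning of related samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

INTERVAL_MIN_SAMPLE_FRACTION = 0.85
INTERVAL_MIN_COVERAGE = 20.0
INTERVAL_PAD_BP = 50

SAMPLE_MIN_CALL_RATE = 0.99
SAMPLE_MIN_MEAN_COVERAGE = 20.0

OUTLIER_N_MADS = 4.0
KINSHIP_CUTOFF = 0.1

# Ploidy bands for karyotype assignment; gaps between bands are ambiguous.
X_SINGLE_MAX = 1.55
X_DOUBLE_MIN, X_DOUBLE_MAX = 1.6, 2.15
X_TRIPLE_MIN = 2.2
Y_ZERO_MAX = 0.06  # exclusive: y < 0.06 means no Y
Y_SINGLE_MAX = 1.3
Y_DOUBLE_MIN = 1.4

#: Sample metrics screened for outliers.
OUTLIER_METRICS = (
    "n_deletions",
    "n_insertions",
    "n_snvs",
    "ins_del_ratio",
    "ti_tv_ratio",
    "het_hom_ratio",
)


# ---------------------------------------------------------------------------
# interval QC


def pad_and_merge_intervals(
    intervals: Sequence[tuple[str, int, int]], pad: int
) -> list[tuple[str, int, int, list[int]]]:
    """Pad intervals by ``pad`` bp each side and merge overlaps.

    Returns merged (contig, start, end, member-indices) with starts clipped
    at 0; member indices refer to the input order.
    """
    padded = [
        (c, max(s - pad, 0), e + pad, i) for i, (c, s, e) in enumerate(intervals)
    ]
    padded.sort(key=lambda t: (t[0], t[1], t[2]))
    merged: list[tuple[str, int, int, list[int]]] = []
    for c, s, e, i in padded:
        if merged and merged[-1][0] == c and s <= merged[-1][2]:
            pc, ps, pe, members = merged[-1]
            merged[-1] = (pc, ps, max(pe, e), members + [i])
        else:
            merged.append((c, s, e, [i]))
    return merged


def interval_qc(
    intervals: Sequence[tuple[str, int, int]],
    coverage: pd.DataFrame,
    frac: float = INTERVAL_MIN_SAMPLE_FRACTION,
    min_cov: float = INTERVAL_MIN_COVERAGE,
    pad: int = INTERVAL_PAD_BP,
) -> pd.DataFrame:
    """Screen padded capture intervals on cross-sample coverage.

    ``coverage`` has one row per input interval (same order) and one column
    per sample. Intervals are padded and merged first; a merged interval's
    per-sample coverage is the length-weighted mean of its members. An
    interval passes when the fraction of samples with coverage >= min_cov is
    >= frac (both boundaries inclusive).
    """
    if coverage.shape[1] == 0:
        raise ValueError("coverage matrix has zero samples")
    if len(coverage) != len(intervals):
        raise ValueError("coverage rows must match intervals")
    lengths = np.array([e - s for _, s, e in intervals], dtype=float)
    merged = pad_and_merge_intervals(intervals, pad)
    rows = []
    for contig, start, end, members in merged:
        w = lengths[members]
        cov = (coverage.iloc[members].to_numpy() * w[:, None]).sum(0) / w.sum()
        good = (cov >= min_cov).mean()
        rows.append(
            {
                "contig": contig,
                "start": start,
                "end": end,
                "frac_samples_covered": good,
                "pass": good >= frac,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sex karyotype


@dataclass(frozen=True)
class PloidyEstimate:
    """Normalized X/Y ploidy (2 x mean sex-chromosome coverage / mean chr20)."""

    sample_id: str
    x_ploidy: float
    y_ploidy: float

    def __post_init__(self) -> None:
        if self.x_ploidy < 0 or self.y_ploidy < 0:
            raise ValueError("ploidy estimates must be non-negative")


def _x_dose(x: float) -> int | None:
    if x <= X_SINGLE_MAX:
        return 1
    if X_DOUBLE_MIN <= x <= X_DOUBLE_MAX:
        return 2
    if x >= X_TRIPLE_MIN:
        return 3
    return None


def _y_dose(y: float) -> int | None:
    if y < Y_ZERO_MAX:
        return 0
    if y <= Y_SINGLE_MAX:
        return 1
    if y >= Y_DOUBLE_MIN:
        return 2
    return None


def impute_sex_karyotype(pe: PloidyEstimate) -> str:
    """Assign a sex karyotype from ploidy bands; band gaps give ``ambiguous``."""
    xd, yd = _x_dose(pe.x_ploidy), _y_dose(pe.y_ploidy)
    if xd is None or yd is None:
        return "ambiguous"
    karyotype = "X" * xd + "Y" * yd
    if xd == 1 and yd == 0:
        karyotype = "X0"
    allowed = {"X0", "XX", "XXX", "XY", "XXY", "XYY", "XXYY"}
    return karyotype if karyotype in allowed else "ambiguous"


# ---------------------------------------------------------------------------
# hard filters


def sample_hard_filters(
    karyotype: str, call_rate: float, mean_coverage: float
) -> tuple[bool, list[str]]:
    """Post-interval-QC sample filters; returns (pass, failure reasons)."""
    reasons = []
    if karyotype not in ("XX", "XY"):
        reasons.append("sex_karyotype")
    if call_rate < SAMPLE_MIN_CALL_RATE:
        reasons.append("call_rate")
    if mean_coverage < SAMPLE_MIN_MEAN_COVERAGE:
        reasons.append("coverage")
    return not reasons, reasons


# ---------------------------------------------------------------------------
# stratified MAD outliers


def mad_outlier_flags(
    metrics: pd.DataFrame,
    strata: pd.Series,
    metric_cols: Sequence[str] = OUTLIER_METRICS,
    n_mads: float = OUTLIER_N_MADS,
) -> pd.DataFrame:
    """Flag samples > n_mads raw MADs from the stratum median of any metric.

    The MAD is unscaled (plain median of absolute deviations, no 1.4826
    consistency factor). Returns a boolean frame per (sample, metric) plus
    an ``any`` column. Constant metrics (MAD 0) flag nothing.
    """
    cols = [c for c in metric_cols if c in metrics.columns]
    flags = pd.DataFrame(False, index=metrics.index, columns=cols)
    for _, idx in metrics.groupby(strata).groups.items():
        sub = metrics.loc[idx, cols]
        med = sub.median()
        mad = (sub - med).abs().median()
        dev = (sub - med).abs()
        flags.loc[idx, cols] = (dev > n_mads * mad) & (mad > 0)
    flags["any"] = flags[cols].any(axis=1)
    return flags


# ---------------------------------------------------------------------------
# maximal independent set


def maximal_independent_set(
    vertices: Sequence[Hashable],
    edges: Iterable[tuple[Hashable, Hashable]],
    priority: Mapping[Hashable, float] | None = None,
) -> set:
    """Greedy maximal independent set, keeping high-priority vertices.

    Repeatedly removes the vertex of currently highest degree; ties are
    broken by removing the lower-priority vertex first, then the smaller
    vertex id. With priority = mean depth this keeps the better-sequenced
    member of each related pair. The result is independent and maximal but
    not necessarily maximum (the exact problem is NP-hard; the greedy
    matches the behavior of the pruning tool the pipeline emulates).
    """
    priority = priority or {}
    adj: dict[Hashable, set] = {v: set() for v in vertices}
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-edge at {a}")
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    full_adj = {v: set(nb) for v, nb in adj.items()}
    alive = set(adj)
    removed: list = []
    while True:
        max_deg = max((len(adj[v]) for v in alive), default=0)
        if max_deg == 0:
            break
        victim = min(
            (v for v in alive if len(adj[v]) == max_deg),
            key=lambda v: (priority.get(v, 0.0), str(v)),
        )
        alive.discard(victim)
        removed.append(victim)
        for nb in adj[victim]:
            adj[nb].discard(victim)
        adj[victim] = set()
    # a removed vertex whose neighbors were all removed later can be re-added
    # without breaking independence; do so greedily (high priority first) so
    # the result is maximal, not just independent
    for v in sorted(removed, key=lambda v: (-priority.get(v, 0.0), str(v))):
        if not full_adj[v] & alive:
            alive.add(v)
    return alive


def prune_related_samples(
    kinship: pd.DataFrame,
    samples: Sequence[str],
    mean_depth: Mapping[str, float] | None = None,
    cutoff: float = KINSHIP_CUTOFF,
) -> set[str]:
    """Keep a maximal set of samples with no kinship above ``cutoff``.

    ``kinship`` columns: sample_i, sample_j, kinship. Samples absent from
    the table are unrelated and always kept.
    """
    edges = [
        (r.sample_i, r.sample_j)
        for r in kinship.itertuples(index=False)
        if r.kinship > cutoff
    ]
    return maximal_independent_set(list(samples), edges, mean_depth)
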