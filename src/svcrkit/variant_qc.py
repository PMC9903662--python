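"""Genotype-level and variant-level quality control.

Implements the "adj" genotype pass criterion (depth, genotype quality, and
heterozygote allele balance), the excess-heterozygosity inbreeding
coefficient, the traditional hard filters used to label false positives
(QD / FS / MQ), the per-site allele-balance binomial feature, assembly of
balanced true/false-positive training sets from trio transmission and array
concordance, and a random-forest site classifier applied at per-class
probability cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier

# Genotype-level ("adj") thresholds.
ADJ_MIN_DP = 10
ADJ_MIN_DP_HAPLOID = 5
ADJ_MIN_GQ = 20
ADJ_MIN_AB = 0.2

# Site-level hard-filter thresholds for false-positive training labels.
HARD_FILTER_MIN_QD = 2.0
HARD_FILTER_MAX_FS = 60.0
HARD_FILTER_MIN_MQ = 30.0

# Excess-heterozygote exclusion.
INBREEDING_COEFF_CUTOFF = -0.3

# Random-forest true-positive probability cutoffs per allele type.
RF_CUTOFF_SNV = 0.061
RF_CUTOFF_INDEL = 0.064

RF_FEATURES = [
    "allele_type",
    "n_alleles",
    "mixed",
    "spanning_deletion",
    "qd",
    "max_ab_p",
    "read_pos_ranksum",
    "mq_ranksum",
]


@dataclass(frozen=True)
class GenotypeObs:
    """One called genotype with the fields the adj filter inspects."""

    ploidy: int
    dp: int
    gq: int
    gt: tuple[int, ...]  # global allele indices
    ad: tuple[int, ...] | None = None  # per-allele depth, index-aligned with site alleles

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2):
            raise ValueError(f"ploidy must be 1 or 2, got {self.ploidy}")
        if self.gq < 0:
            raise ValueError("GQ must be non-negative")
        if len(self.gt) != self.ploidy:
            raise ValueError("|GT| must equal ploidy")

    @property
    def is_het(self) -> bool:
        return self.ploidy == 2 and self.gt[0] != self.gt[1]


def adj_filter(g: GenotypeObs) -> tuple[bool, str | None]:
    """Apply the adj criteria: DP >= 10 (5 haploid), GQ >= 20, het balance > 0.2.

    The balance requirement applies to every alternate allele carried by a
    heterozygous genotype, as a fraction of the genotype's total allelic
    depth. Returns (pass, reason-code-if-failed).
    """
    min_dp = ADJ_MIN_DP_HAPLOID if g.ploidy == 1 else ADJ_MIN_DP
    if g.dp < min_dp:
        return False, "low_dp"
    if g.gq < ADJ_MIN_GQ:
        return False, "low_gq"
    if g.is_het:
        if g.ad is None:
            return False, "missing_ad"
        total = sum(g.ad)
        if total <= 0:
            return False, "missing_ad"
        for allele in set(g.gt):
            if allele == 0:
                continue
            if g.ad[allele] / total <= ADJ_MIN_AB:
                return False, "allele_balance"
    return True, None


def inbreeding_coefficient(genotypes: Iterable[tuple[int, int]]) -> float | None:
    """F = 1 - observed het / expected het at a biallelic site.

    ``genotypes`` are called diploid genotypes as (a, b) allele pairs with
    alleles in {0, 1}. Expected heterozygosity is 2 p (1-p) n over called
    genotypes. Returns None when the site is monomorphic (expected het 0),
    in which case the site is not flagged.
    """
    gts = list(genotypes)
    if not gts:
        raise ValueError("need at least one called genotype")
    n = len(gts)
    alt = sum(a + b for a, b in gts)
    p = alt / (2 * n)
    expected = 2.0 * p * (1.0 - p) * n
    if expected == 0:
        return None
    observed = sum(1 for a, b in gts if a != b)
    return 1.0 - observed / expected


def fails_inbreeding(f: float | None) -> bool:
    return f is not None and f < INBREEDING_COEFF_CUTOFF


def hard_filter_label(qd: float, fs: float, mq: float) -> bool:
    """True iff the site fails the traditional hard filters (FP label).

    Fail when QD < 2, FS > 60, or MQ < 30; missing values must be handled by
    the caller (sites missing any field are excluded from training).
    """
    for v in (qd, fs, mq):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError("QD/FS/MQ must be present to hard-filter a site")
    return qd < HARD_FILTER_MIN_QD or fs > HARD_FILTER_MAX_FS or mq < HARD_FILTER_MIN_MQ


def max_ab_binomial_p(het_ads: Sequence[tuple[int, int]]) -> float:
    """Maximum over heterozygotes of the exact two-sided binomial p at 0.5.

    Each heterozygote contributes the probability of its (ref, alt) depth
    split under Binomial(ref+alt, 0.5), two-sided by summing outcomes no
    more probable than the observed one.
    """
    if not het_ads:
        raise ValueError("need at least one heterozygote")
    best = 0.0
    for ref_dp, alt_dp in het_ads:
        n = ref_dp + alt_dp
        if n == 0:
            p = 1.0
        else:
            p = binomtest(alt_dp, n, 0.5).pvalue
        best = max(best, p)
    return best


# ---------------------------------------------------------------------------
# training-set assembly


def _relation_pairs(pedigree: pd.DataFrame) -> tuple[set[frozenset], set[frozenset]]:
    """Parent-offspring and full-sibling pairs from a 6-column PED table."""
    parent_child: set[frozenset] = set()
    parents_of: dict[str, tuple[str, str]] = {}
    for row in pedigree.itertuples(index=False):
        iid, father, mother = str(row.iid), str(row.father), str(row.mother)
        if father != "0":
            parent_child.add(frozenset((iid, father)))
        if mother != "0":
            parent_child.add(frozenset((iid, mother)))
        if father != "0" and mother != "0":
            parents_of[iid] = (father, mother)
    siblings: set[frozenset] = set()
    kids = list(parents_of)
    for i, a in enumerate(kids):
        for b in kids[i + 1 :]:
            if parents_of[a] == parents_of[b]:
                siblings.add(frozenset((a, b)))
    return parent_child, siblings


def assemble_training_sets(
    genotypes: np.ndarray,
    variant_keys: Sequence[str],
    samples: Sequence[str],
    pedigree: pd.DataFrame,
    hard_filter_fail_keys: Sequence[str],
    concordance: pd.DataFrame | None = None,
    truth_keys: Sequence[str] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Label variants true/false positive for classifier training.

    True positives: transmitted singletons (carried by exactly one
    parent-offspring pair), sibling singletons, array variants that are
    common (AF > 0.1%) and concordant (> 90% non-reference concordance), and
    any externally supplied truth keys. False positives: hard-filter
    failures. The larger set is randomly downsampled (seeded, without
    replacement) so the two classes are balanced.

    ``concordance`` columns: key, af, concordance.
    """
    known = set(samples)
    ped_ids = set(pedigree["iid"].astype(str))
    if not ped_ids <= known:
        raise ValueError(f"pedigree ids not in cohort: {sorted(ped_ids - known)[:5]}")
    parent_child, siblings = _relation_pairs(pedigree)

    tp: dict[str, str] = {}
    for i, key in enumerate(variant_keys):
        carriers = np.nonzero(genotypes[i] > 0)[0]
        if len(carriers) != 2:
            continue
        pair = frozenset((samples[carriers[0]], samples[carriers[1]]))
        if pair in parent_child:
            tp.setdefault(key, "transmitted_singleton")
        elif pair in siblings:
            tp.setdefault(key, "sibling_singleton")
    if concordance is not None:
        ok = concordance[
            (concordance["af"] > 0.001) & (concordance["concordance"] > 0.9)
        ]
        for key in ok["key"]:
            tp.setdefault(key, "concordant_array")
    for key in truth_keys:
        tp.setdefault(key, "external_truth")

    fp_keys = [k for k in hard_filter_fail_keys if k not in tp]
    if not tp:
        raise ValueError("empty true-positive training set; cannot balance classes")

    rng = np.random.default_rng(seed)
    tp_items = sorted(tp.items())
    n = min(len(tp_items), len(fp_keys))
    if n == 0:
        raise ValueError("empty false-positive training set; cannot balance classes")
    if len(fp_keys) > n:
        fp_keys = list(rng.choice(np.array(fp_keys, dtype=object), size=n, replace=False))
    if len(tp_items) > n:
        idx = rng.choice(len(tp_items), size=n, replace=False)
        tp_items = [tp_items[i] for i in sorted(idx)]

    rows = [
        {"key": k, "label": "true_positive", "source": src} for k, src in tp_items
    ] + [
        {"key": k, "label": "false_positive", "source": "hard_filter_fail"}
        for k in fp_keys
    ]
    return pd.DataFrame(rows, columns=["key", "label", "source"])


# ---------------------------------------------------------------------------
# random-forest classifier


def _feature_matrix(features: pd.DataFrame) -> np.ndarray:
    x = pd.DataFrame(index=features.index)
    x["is_indel"] = (features["allele_type"] == "indel").astype(float)
    x["n_alleles"] = features["n_alleles"].astype(float)
    x["mixed"] = features["mixed"].astype(float)
    x["spanning_deletion"] = features["spanning_deletion"].astype(float)
    x["qd"] = features["qd"].astype(float)
    x["max_ab_p"] = features["max_ab_p"].astype(float)
    # rank-sum features need per-read data; when absent they are imputed at 0
    # with a companion missingness indicator so the forest can ignore them
    for col in ("read_pos_ranksum", "mq_ranksum"):
        vals = features[col].astype(float) if col in features else pd.Series(np.nan, index=features.index)
        x[col] = vals.fillna(0.0)
        x[col + "_missing"] = vals.isna().astype(float)
    return x.to_numpy()


def train_apply_rf(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    inbreeding: Mapping[str, float | None],
    has_adj_nonref: Mapping[str, bool],
    snv_cutoff: float = RF_CUTOFF_SNV,
    indel_cutoff: float = RF_CUTOFF_INDEL,
    seed: int = 0,
    n_estimators: int = 200,
) -> pd.DataFrame:
    """Train a random forest on labeled sites and score every variant.

    A variant passes when its predicted true-positive probability meets the
    per-class cutoff AND it survives the two hard exclusions: inbreeding
    coefficient < -0.3 (excess heterozygotes) and "no sample carries an
    adj-pass non-reference genotype".

    ``features`` must contain a ``key`` column plus the RF feature columns;
    returns a table with rf_prob, pass/fail, and the failure reasons.
    """
    merged = features.merge(labels, on="key", how="inner")
    classes = merged["label"].unique()
    if len(classes) < 2:
        raise ValueError("training labels contain a single class; cannot train")
    x_train = _feature_matrix(merged)
    y_train = (merged["label"] == "true_positive").to_numpy()

    rf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    rf.fit(x_train, y_train)
    prob = rf.predict_proba(_feature_matrix(features))[:, list(rf.classes_).index(True)]

    out = features[["key", "allele_type"]].copy()
    out["rf_prob"] = prob
    cutoff = np.where(out["allele_type"] == "indel", indel_cutoff, snv_cutoff)
    out["rf_pass"] = out["rf_prob"] >= cutoff
    out["fails_inbreeding"] = [
        fails_inbreeding(inbreeding.get(k)) for k in out["key"]
    ]
    out["no_adj_carrier"] = [not has_adj_nonref.get(k, False) for k in out["key"]]
    out["pass"] = out["rf_pass"] & ~out["fails_inbreeding"] & ~out["no_adj_carrier"]
    return out
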