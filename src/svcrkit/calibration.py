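"""Random-phenotype simulation, score tests, and summary-statistic calibration.

The calibration strategy: simulate phenotypes with no true genotype effect
but realistic familial correlation (multivariate normal with covariance
h2 * GRM + (1 - h2) * I), run the association machinery on them, and use the
resulting null p-value distributions to (a) check test calibration via the
genomic-control inflation factor lambda, (b) derive empirical significance
thresholds from the median most-significant p per phenotype, and (c) define
power-based filters (expected allele count) and calibration filters
(lambda cutoffs, zero standard errors) for real summary statistics.

Association tests here are lightweight score tests from linear or logistic
null models with covariates — stand-ins that exercise every downstream
filter; mixed-model machinery is intentionally not reimplemented, and
externally computed group-test p-values can be ingested alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sample_qc import maximal_independent_set
from .synthetic import Grm

#: Median chi-square(1) — the genomic-control denominator.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

EXPECTED_AC_THRESHOLD = 50.0
LAMBDA_GC_CUTOFF = 0.75
GENE_MIN_COVERAGE = 20.0
PHENO_R2_CUTOFF = 0.5
MAX_MAF_GROUP_TEST = 0.01
MIN_VARIANTS_PER_GROUP = 2
ALPHA_PER_PHENOTYPE = 0.05


@dataclass
class PhenotypeMatrix:
    """Simulated or real phenotypes plus per-column metadata.

    ``values``: samples x phenotypes frame (binary columns hold {0,1,NaN}).
    ``meta``: per-phenotype rows with trait_type ('continuous'|'binary'),
    h2, prevalence (NaN for continuous), n_cases, n_defined.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.meta.index):
            raise ValueError("values columns and meta index must align")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def priority(self, pheno: str) -> float:
        """Tie-break weight for pruning: cases for binary, defined for continuous."""
        row = self.meta.loc[pheno]
        return float(
            row["n_cases"] if row["trait_type"] == "binary" else row["n_defined"]
        )


def simulate_random_phenotypes(
    grm: Grm,
    n: int,
    heritabilities: Sequence[float],
    prevalences: Sequence[float] = (),
    seed: int = 0,
) -> PhenotypeMatrix:
    """Simulate GRM-correlated random phenotypes.

    The genetic component g is multivariate normal with covariance GRM
    (sampled through its Cholesky factor, with a small diagonal jitter for
    near-singular matrices) and y = sqrt(h2) g + sqrt(1 - h2) eps with eps
    i.i.d. standard normal. ``n`` continuous columns cycle through
    ``heritabilities``; each prevalence adds one binary column at
    heritability 1, thresholded at the empirical (1 - prevalence) quantile
    so the case count is exactly floor(prevalence * n_samples).
    """
    for h2 in heritabilities:
        if not 0.0 <= h2 <= 1.0:
            raise ValueError(f"heritability must be in [0, 1], got {h2}")
    for prev in prevalences:
        if not 0.0 < prev <= 0.5:
            raise ValueError(f"prevalence must be in (0, 0.5], got {prev}")
    if n > 0 and not heritabilities:
        raise ValueError("need at least one heritability for continuous phenotypes")

    rng = np.random.default_rng(seed)
    n_samples = len(grm.sample_ids)
    chol = grm.cholesky()

    cols: dict[str, np.ndarray] = {}
    meta_rows = []

    def genetic_component() -> np.ndarray:
        return chol @ rng.standard_normal(n_samples)

    for j in range(n):
        h2 = float(heritabilities[j % len(heritabilities)])
        y = np.sqrt(h2) * genetic_component() + np.sqrt(1.0 - h2) * rng.standard_normal(
            n_samples
        )
        name = f"continuous_{j:04d}"
        cols[name] = y
        meta_rows.append(
            {
                "phenotype": name,
                "trait_type": "continuous",
                "h2": h2,
                "prevalence": np.nan,
                "n_cases": np.nan,
                "n_defined": n_samples,
                "seed": seed,
            }
        )

    for k, prev in enumerate(prevalences):
        y = genetic_component()  # h2 = 1 for binary liabilities
        n_cases = int(np.floor(prev * n_samples))
        order = np.argsort(y)[::-1]
        z = np.zeros(n_samples)
        z[order[:n_cases]] = 1.0
        name = f"binary_{k:04d}"
        cols[name] = z
        meta_rows.append(
            {
                "phenotype": name,
                "trait_type": "binary",
                "h2": 1.0,
                "prevalence": prev,
                "n_cases": n_cases,
                "n_defined": n_samples,
                "seed": seed,
            }
        )

    values = pd.DataFrame(cols, index=list(grm.sample_ids))
    meta = pd.DataFrame(meta_rows).set_index("phenotype")
    return PhenotypeMatrix(values, meta)


# ---------------------------------------------------------------------------
# score tests


class ScoreTester:
    """Score tests of genotype dosages against one phenotype with covariates.

    The null model (phenotype ~ covariates) is fitted once; each variant is
    then scored in O(n). Continuous traits use a linear model, binary traits
    a logistic one. Samples with missing phenotype are dropped.
    """

    def __init__(
        self,
        y: np.ndarray,
        covariates: np.ndarray | None = None,
        trait_type: str = "continuous",
    ) -> None:
        y = np.asarray(y, dtype=float)
        self.mask = ~np.isnan(y)
        self.y = y[self.mask]
        n = len(self.y)
        if covariates is None:
            x = np.ones((n, 1))
        else:
            covariates = np.asarray(covariates, dtype=float)[self.mask]
            x = np.column_stack([np.ones(n), covariates])
        self.x = x
        self.trait_type = trait_type
        if trait_type == "continuous":
            self.q, _ = np.linalg.qr(x)
            resid = self.y - self.q @ (self.q.T @ self.y)
            self.resid = resid
            self.sigma2 = float(resid @ resid) / (n - x.shape[1])
        elif trait_type == "binary":
            import statsmodels.api as sm

            fit = sm.GLM(self.y, x, family=sm.families.Binomial()).fit()
            self.mu = fit.fittedvalues
            self.w = self.mu * (1.0 - self.mu)
            self.resid = self.y - self.mu
            xtw = x.T * self.w
            self.xtwx_inv = np.linalg.inv(xtw @ x)
            self.xtw = xtw
        else:
            raise ValueError(f"unknown trait type {trait_type}")

    def test_many(self, genotypes: np.ndarray) -> pd.DataFrame:
        """Score-test each column of ``genotypes`` (n_samples x n_variants).

        Returns p, beta, se, and a validity flag; variants with zero
        genotype variance among phenotyped samples are flagged and skipped.
        """
        g = np.asarray(genotypes, dtype=float)[self.mask]
        if g.ndim == 1:
            g = g[:, None]
        var_ok = g.std(axis=0) > 0
        if self.trait_type == "continuous":
            g_perp = g - self.q @ (self.q.T @ g)
            denom = np.einsum("ij,ij->j", g_perp, g_perp)
            u = g_perp.T @ self.y
            with np.errstate(divide="ignore", invalid="ignore"):
                beta = u / denom
                se = np.sqrt(self.sigma2 / denom)
                chi2 = u**2 / (self.sigma2 * denom)
        else:
            u = g.T @ self.resid
            gtw = g.T * self.w
            gtwx = gtw @ self.x
            v = np.einsum("ij,ij->i", gtw, g.T) - np.einsum(
                "ij,ij->i", gtwx @ self.xtwx_inv, gtwx
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                beta = u / v
                se = 1.0 / np.sqrt(v)
                chi2 = u**2 / v
        p = stats.chi2.sf(chi2, 1)
        return pd.DataFrame(
            {
                "p": np.where(var_ok, p, np.nan),
                "beta": np.where(var_ok, beta, np.nan),
                "se": np.where(var_ok, se, np.nan),
                "valid": var_ok,
            }
        )


def single_variant_score_test(
    genotype: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    trait_type: str = "continuous",
) -> tuple[float, float, float]:
    """One-variant convenience wrapper; raises on zero genotype variance."""
    res = ScoreTester(phenotype, covariates, trait_type).test_many(genotype).iloc[0]
    if not res["valid"]:
        raise ValueError("variant has zero genotype variance among phenotyped samples")
    return float(res["p"]), float(res["beta"]), float(res["se"])


def burden_score(
    genotypes: np.ndarray, afs: np.ndarray, max_maf: float = MAX_MAF_GROUP_TEST
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample sum of minor-allele counts over qualifying rare variants.

    Returns (burden vector, qualifying-variant mask). A variant qualifies
    when its minor allele frequency is <= max_maf; for variants where the
    alternate is the major allele the minor-allele count is 2 - dosage.
    """
    afs = np.asarray(afs, dtype=float)
    maf = np.minimum(afs, 1.0 - afs)
    keep = maf <= max_maf
    g = np.asarray(genotypes, dtype=float)
    minor = np.where(afs[:, None] <= 0.5, g, 2.0 - g)
    return minor[keep].sum(axis=0), keep


def burden_test(
    genotypes: np.ndarray,
    afs: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    trait_type: str = "continuous",
    max_maf: float = MAX_MAF_GROUP_TEST,
) -> tuple[float, float, float]:
    """Score test of a gene-class burden against a phenotype.

    ``genotypes`` is variants x samples for the group's members. Requires at
    least two qualifying variants (MAF <= max_maf); otherwise the group is
    excluded with a ValueError carrying the reason.
    """
    score, keep = burden_score(genotypes, afs, max_maf)
    if keep.sum() < MIN_VARIANTS_PER_GROUP:
        raise ValueError(
            f"group excluded: {int(keep.sum())} qualifying variants "
            f"(minimum {MIN_VARIANTS_PER_GROUP} at MAF <= {max_maf})"
        )
    return single_variant_score_test(score, phenotype, covariates, trait_type)


# ---------------------------------------------------------------------------
# lambda GC and filters


def lambda_gc(p_values: Sequence[float]) -> float:
    """Genomic-control inflation: median chi-square over the null median.

    p-values are transformed through the chi-square(1) quantile function;
    lambda = 1 for perfectly calibrated tests, < 1 for deflation.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("lambda GC of an empty p-value set is undefined")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def expected_allele_count(freq: np.ndarray, n_eff: np.ndarray) -> np.ndarray:
    """Expected AC = frequency (CAF or MAF) x cases (or defined, continuous)."""
    return np.asarray(freq, dtype=float) * np.asarray(n_eff, dtype=float)


def expected_ac_filter(
    records: pd.DataFrame, threshold: float = EXPECTED_AC_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records whose expected allele count is below ``threshold``.

    ``records`` needs columns ``freq`` (CAF for genes, MAF for variants) and
    ``n_eff`` (cases for binary traits, defined samples for continuous).
    Records with missing frequency are removed with reason ``missing_freq``.
    Returns (retained, removed-with-reason).
    """
    rec = records.copy()
    rec["expected_ac"] = expected_allele_count(rec["freq"], rec["n_eff"])
    missing = rec["freq"].isna()
    low = ~missing & (rec["expected_ac"] < threshold)
    removed = rec[missing | low].copy()
    removed["removed_reason"] = np.where(missing[missing | low], "missing_freq", "low_expected_ac")
    return rec[~(missing | low)].copy(), removed


def empirical_thresholds(
    min_p_per_phenotype: Sequence[float], alpha: float = ALPHA_PER_PHENOTYPE
) -> tuple[float, float]:
    """Effective test count and significance threshold from null phenotypes.

    The most significant p of a null phenotype estimates the inverse of the
    effective number of independent tests; the median across phenotypes,
    p-tilde, gives (effective tests, threshold) = (1 / p-tilde,
    alpha * p-tilde), i.e. about ``alpha`` expected false positives per
    phenotype at the returned threshold.
    """
    p = np.asarray(min_p_per_phenotype, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one simulated phenotype")
    p_tilde = float(np.median(p))
    return 1.0 / p_tilde, alpha * p_tilde


# ---------------------------------------------------------------------------
# summary-statistic QC gate


def phenotype_lambda_table(records: pd.DataFrame) -> pd.Series:
    """Lambda GC per phenotype over all its association records."""
    return records.groupby("phenotype")["p"].apply(lambda_gc)


def gene_synonymous_lambda_table(records: pd.DataFrame) -> pd.Series:
    """Per-gene lambda GC across phenotypes, from synonymous-class records."""
    syn = records[records["functional_class"] == "synonymous"]
    return syn.groupby("gene")["p"].apply(lambda_gc)


def qc_gate(
    records: pd.DataFrame,
    gene_table: pd.DataFrame,
    phenotype_lambdas: Mapping[str, float],
    ac_threshold: float = EXPECTED_AC_THRESHOLD,
    lambda_cutoff: float = LAMBDA_GC_CUTOFF,
    min_gene_coverage: float = GENE_MIN_COVERAGE,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the summary-statistic retention rules; return records + audit.

    Drops, in order: records with SE = 0 (invalid); records failing the
    expected-allele-count filter; all records of genes with mean coverage
    below ``min_gene_coverage`` or synonymous-class lambda below
    ``lambda_cutoff``; all records of phenotypes with lambda below
    ``lambda_cutoff``. ``gene_table`` rows: gene, mean_coverage,
    synonymous_lambda (NaN lambda means not assessable, kept). The gate is a
    pure filter over its inputs, so applying it twice equals applying once.
    """
    audit: dict[str, int] = {}
    rec = records.copy()

    se_zero = rec["se"].fillna(0.0) == 0.0
    audit["se_zero"] = int(se_zero.sum())
    rec = rec[~se_zero]

    kept, removed = expected_ac_filter(rec, ac_threshold)
    audit["expected_ac"] = len(removed)
    rec = kept

    bad_cov = set(gene_table.loc[gene_table["mean_coverage"] < min_gene_coverage, "gene"])
    lam = gene_table.set_index("gene")["synonymous_lambda"]
    bad_lambda = set(lam[lam < lambda_cutoff].index)
    if "gene" in rec.columns:
        drop_gene = rec["gene"].isin(bad_cov | bad_lambda)
        audit["gene_coverage"] = int(rec["gene"].isin(bad_cov).sum())
        audit["gene_synonymous_lambda"] = int(
            (rec["gene"].isin(bad_lambda) & ~rec["gene"].isin(bad_cov)).sum()
        )
        rec = rec[~drop_gene]

    lam_p = pd.Series(dict(phenotype_lambdas))
    bad_pheno = set(lam_p[lam_p < lambda_cutoff].index)
    drop_pheno = rec["phenotype"].isin(bad_pheno)
    audit["phenotype_lambda"] = int(drop_pheno.sum())
    rec = rec[~drop_pheno]

    audit["retained"] = len(rec)
    return rec.reset_index(drop=True), audit


# ---------------------------------------------------------------------------
# phenotype pruning


def prune_correlated_phenotypes(
    pm: PhenotypeMatrix, r2_cutoff: float = PHENO_R2_CUTOFF
) -> tuple[set[str], pd.DataFrame]:
    """Keep a maximal set of phenotypes with pairwise r^2 <= cutoff.

    Pearson correlation is computed on standardized columns with missing
    values mean-imputed (i.e. set to 0 after standardization); pairs with
    r^2 above the cutoff become edges and a greedy maximal independent set
    preferring phenotypes with more cases (more defined values for
    continuous traits) is retained. Zero-variance columns are excluded from
    the correlation and flagged but kept. Returns (kept set, edge table).
    """
    if pm.values.shape[1] < 2:
        raise ValueError("need at least two phenotypes to prune")
    vals = pm.values.to_numpy(dtype=float)
    names = list(pm.values.columns)
    mean = np.nanmean(vals, axis=0)
    std = np.nanstd(vals, axis=0)
    ok = std > 0
    z = (vals - mean) / np.where(ok, std, 1.0)
    z = np.nan_to_num(z, nan=0.0)
    r = (z.T @ z) / len(z)
    r2 = r**2

    edges = []
    idx = np.nonzero(ok)[0]
    for a_pos, i in enumerate(idx):
        for j in idx[a_pos + 1 :]:
            if r2[i, j] > r2_cutoff:
                edges.append((names[i], names[j], r2[i, j]))
    edge_table = pd.DataFrame(edges, columns=["pheno_i", "pheno_j", "r2"])
    priority = {name: pm.priority(name) for name in names}
    kept = maximal_independent_set(
        names, [(a, b) for a, b, _ in edges], priority
    )
    return set(kept), edge_table
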