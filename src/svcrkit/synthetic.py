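"""Synthetic exome cohorts with the structure the QC and calibration steps assume.

This module manufactures every input the rest of the package consumes:
single-sample gVCFs that tile small contigs with reference blocks and
variant records, trio pedigrees with Mendelian transmission, a sparse
family-block genetic relatedness matrix (GRM), gene/functional-class
annotation tables with a rare-skewed site-frequency spectrum, per-site QC
statistics, and interval coverage matrices.

The generative model is deliberately simple: site positions are uniform at
a per-base rate, true alternate-allele frequencies are Beta-distributed,
founder genotypes are Hardy-Weinberg draws, trio offspring inherit one
allele from each parent (with an optional de novo rate), read depth is
Poisson around the target mean, and allelic depths/genotype likelihoods come
from a symmetric per-read error model. Everything is driven by a single
seeded generator, so identical specs produce byte-identical files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .gvcf_io import NON_REF, GvcfRecord, write_gvcf
from .svcr import allele_sort_key, genotype_tuples

_BASES = "ACGT"
FUNCTIONAL_CLASSES = ("pLoF", "missense|LC", "synonymous")
#: Default class mix: rare pLoF scarcer than missense, synonymous in between,
#: echoing the qualitative exome spectrum.
DEFAULT_CLASS_PROBS = (0.08, 0.55, 0.37)


def reference_base(contig: str, pos: int) -> str:
    """Deterministic, seed-independent reference base so all samples agree."""
    return _BASES[zlib.crc32(f"{contig}:{pos}".encode()) & 3]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``n_trios`` trios occupy the first ``3 * n_trios`` samples in
    (father, mother, offspring) order; the rest are unrelated founders.
    """

    n_samples: int
    n_trios: int = 0
    contigs: tuple[tuple[str, int], ...] = (("chr1", 5000), ("chr2", 5000))
    variant_rate: float = 0.02
    # rare-skewed site-frequency spectrum: most variants rare, a tail of
    # common ones, echoing an exome cohort's qualitative spectrum
    af_beta: tuple[float, float] = (0.15, 4.0)
    mean_depth: float = 30.0
    seed: int = 0
    multiallelic_rate: float = 0.05
    insertion_rate: float = 0.15
    denovo_rate: float = 0.0
    error_rate: float = 1e-3

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError(f"n_samples must be positive, got {self.n_samples}")
        if self.n_trios < 0 or 3 * self.n_trios > self.n_samples:
            raise ValueError(
                f"need 3*n_trios <= n_samples, got {self.n_trios} trios "
                f"for {self.n_samples} samples"
            )
        for name, length in self.contigs:
            if length < 1:
                raise ValueError(f"contig {name} length must be >= 1, got {length}")
        for label, rate in (
            ("variant_rate", self.variant_rate),
            ("multiallelic_rate", self.multiallelic_rate),
            ("insertion_rate", self.insertion_rate),
            ("denovo_rate", self.denovo_rate),
            ("error_rate", self.error_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{label} must be in [0, 1], got {rate}")
        if self.mean_depth <= 0:
            raise ValueError(f"mean_depth must be positive, got {self.mean_depth}")
        if min(self.af_beta) <= 0:
            raise ValueError(f"af_beta shapes must be positive, got {self.af_beta}")


@dataclass
class Site:
    """A true polymorphic site: one ref base and one or more alternates."""

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    afs: tuple[float, ...]  # one per alternate


@dataclass
class Cohort:
    """A generated cohort: truth, per-sample gVCF records, pedigree, intervals."""

    spec: CohortSpec
    samples: list[str]
    sites: list[Site]
    variants: pd.DataFrame  # one row per (site, alt): contig,pos,ref,alt,key,true_af
    genotypes: np.ndarray  # (n_variant_rows, n_samples) dosage of that alt
    gvcfs: dict[str, list[GvcfRecord]]
    pedigree: pd.DataFrame  # 6-column PED
    intervals: list[tuple[str, int, int]]  # 0-based half-open

    @property
    def contigs(self) -> list[tuple[str, int]]:
        return list(self.spec.contigs)

    def empirical_af(self) -> np.ndarray:
        """Alternate-allele frequency of each variant row from the truth matrix."""
        n_chrom = 2 * len(self.samples)
        return self.genotypes.sum(axis=1) / n_chrom


@dataclass
class Grm:
    """Sparse symmetric PSD kinship-like relatedness matrix."""

    sample_ids: list[str]
    matrix: sp.csr_matrix

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())

    def cholesky(self, jitter: float = 1e-8) -> np.ndarray:
        """Lower-triangular factor; raises if the matrix is not PSD."""
        dense = self.to_dense()
        if not np.allclose(dense, dense.T):
            raise ValueError("GRM is not symmetric")
        try:
            return np.linalg.cholesky(dense + jitter * np.eye(len(self.sample_ids)))
        except np.linalg.LinAlgError:
            raise ValueError(
                "GRM is not positive semi-definite (Cholesky factorization failed)"
            ) from None


# ---------------------------------------------------------------------------
# site and genotype simulation


def _draw_sites(spec: CohortSpec, rng: np.random.Generator) -> list[Site]:
    sites: list[Site] = []
    for contig, length in spec.contigs:
        n = rng.binomial(length, spec.variant_rate)
        positions = np.sort(rng.choice(length, size=n, replace=False))
        for pos in positions:
            ref = reference_base(contig, int(pos))
            n_alts = 2 if rng.random() < spec.multiallelic_rate else 1
            alts: list[str] = []
            while len(alts) < n_alts:
                if rng.random() < spec.insertion_rate:
                    ins = "".join(rng.choice(list(_BASES), size=rng.integers(1, 4)))
                    alt = ref + ins
                else:
                    alt = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]
                if alt not in alts:
                    alts.append(alt)
            alts.sort(key=allele_sort_key)
            while True:
                afs = rng.beta(*spec.af_beta, size=n_alts)
                if afs.sum() < 0.95:
                    break
            sites.append(Site(contig, int(pos), ref, tuple(alts), tuple(afs)))
    return sites


def _draw_genotypes(
    spec: CohortSpec, sites: list[Site], rng: np.random.Generator
) -> np.ndarray:
    """Per-site diploid allele pairs: array (n_sites, n_samples, 2) of indices."""
    n = spec.n_samples
    geno = np.zeros((len(sites), n, 2), dtype=np.int64)
    founder = np.ones(n, dtype=bool)
    for t in range(spec.n_trios):
        founder[3 * t + 2] = False  # offspring
    for i, site in enumerate(sites):
        probs = np.array([1.0 - sum(site.afs), *site.afs])
        geno[i, founder] = rng.choice(len(probs), size=(int(founder.sum()), 2), p=probs)
        for t in range(spec.n_trios):
            fa, mo, ch = 3 * t, 3 * t + 1, 3 * t + 2
            geno[i, ch, 0] = geno[i, fa, rng.integers(2)]
            geno[i, ch, 1] = geno[i, mo, rng.integers(2)]
            if spec.denovo_rate > 0:
                for hap in range(2):
                    if rng.random() < spec.denovo_rate:
                        others = [
                            a for a in range(len(probs)) if a != geno[i, ch, hap]
                        ]
                        geno[i, ch, hap] = others[rng.integers(len(others))]
        geno[i] = np.sort(geno[i], axis=-1)
    return geno


def _genotype_likelihoods(
    ad: np.ndarray, n_alleles: int, error_rate: float
) -> np.ndarray:
    """Phred-scaled, min-normalized PL over diploid genotypes from read counts."""
    e = error_rate
    emission = np.full((n_alleles, n_alleles), e / (n_alleles - 1))
    np.fill_diagonal(emission, 1.0 - e)
    pls = []
    for a, b in genotype_tuples(n_alleles, 2):
        p = 0.5 * emission[a] + 0.5 * emission[b]
        pls.append(-10.0 * (ad * np.log10(p)).sum())
    arr = np.array(pls)
    return np.rint(arr - arr.min()).astype(np.int64)


def _variant_record(
    site: Site,
    pair: tuple[int, int],
    mean_depth: float,
    error_rate: float,
    rng: np.random.Generator,
) -> GvcfRecord:
    carried = sorted({a for a in pair if a > 0})
    local_alleles = [site.ref] + [site.alts[a - 1] for a in carried] + [NON_REF]
    to_local = {0: 0, **{g: i + 1 for i, g in enumerate(carried)}}
    gt = tuple(sorted(to_local[a] for a in pair))
    n_local = len(local_alleles)

    dp = int(rng.poisson(mean_depth))
    e = error_rate
    emission = np.full((n_local, n_local), e / (n_local - 1))
    np.fill_diagonal(emission, 1.0 - e)
    read_probs = 0.5 * emission[gt[0]] + 0.5 * emission[gt[1]]
    ad = rng.multinomial(dp, read_probs) if dp > 0 else np.zeros(n_local, dtype=int)
    pl = _genotype_likelihoods(ad, n_local, error_rate)
    nonbest = np.delete(pl, np.argmin(pl))
    gq = int(min(nonbest.min() if nonbest.size else 0, 99))
    return GvcfRecord(
        contig=site.contig,
        pos=site.pos,
        ref=site.ref,
        alts=tuple(local_alleles[1:]),
        gt=gt,
        gq=gq,
        dp=dp,
        ad=tuple(int(x) for x in ad),
        pl=tuple(int(x) for x in pl),
    )


def _emit_blocks(
    contig: str,
    start: int,
    stop: int,
    mean_depth: float,
    rng: np.random.Generator,
    out: list[GvcfRecord],
) -> None:
    pos = start
    while pos < stop:
        length = int(min(rng.integers(30, 300), stop - pos))
        gq = int(np.clip(rng.normal(55.0, 18.0), 0, 99))
        dp = max(int(rng.poisson(mean_depth)), 0)
        out.append(
            GvcfRecord(
                contig=contig,
                pos=pos,
                ref=reference_base(contig, pos),
                alts=(),
                gt=(0, 0),
                gq=gq,
                dp=dp,
                end=pos + length,
            )
        )
        pos += length


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate gVCFs, pedigree, truth genotypes, and capture intervals.

    Each sample's gVCF tiles every contig exactly once with alternating
    reference blocks and variant records; with a de novo rate of zero, trio
    offspring are Mendelian-consistent by construction. Identical specs
    (including seed) give identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    samples = [f"S{i:04d}" for i in range(spec.n_samples)]
    sites = _draw_sites(spec, rng)
    geno = _draw_genotypes(spec, sites, rng)

    # truth table: one row per (site, alt)
    rows = []
    dosages = []
    for i, site in enumerate(sites):
        for j, alt in enumerate(site.alts):
            rows.append(
                {
                    "contig": site.contig,
                    "pos": site.pos,
                    "ref": site.ref,
                    "alt": alt,
                    "key": f"{site.contig}:{site.pos + 1}:{site.ref}:{alt}",
                    "true_af": site.afs[j],
                }
            )
            dosages.append((geno[i] == j + 1).sum(axis=-1))
    variants = pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "alt", "key", "true_af"]
    )
    genotypes = (
        np.array(dosages, dtype=np.int64)
        if dosages
        else np.zeros((0, spec.n_samples), dtype=np.int64)
    )

    site_index: dict[str, list[int]] = {name: [] for name, _ in spec.contigs}
    for i, site in enumerate(sites):
        site_index[site.contig].append(i)

    gvcfs: dict[str, list[GvcfRecord]] = {}
    for s_idx, sample in enumerate(samples):
        records: list[GvcfRecord] = []
        for contig, length in spec.contigs:
            pos = 0
            for i in site_index[contig]:
                site = sites[i]
                pair = tuple(geno[i, s_idx])
                if pair == (0, 0):
                    continue
                _emit_blocks(contig, pos, site.pos, spec.mean_depth, rng, records)
                records.append(
                    _variant_record(site, pair, spec.mean_depth, spec.error_rate, rng)
                )
                pos = site.pos + 1
            _emit_blocks(contig, pos, length, spec.mean_depth, rng, records)
        gvcfs[sample] = records

    ped_rows = []
    for t in range(spec.n_trios):
        fa, mo, ch = samples[3 * t], samples[3 * t + 1], samples[3 * t + 2]
        fam = f"FAM{t:03d}"
        ped_rows.append((fam, fa, "0", "0", 1, -9))
        ped_rows.append((fam, mo, "0", "0", 2, -9))
        ped_rows.append((fam, ch, fa, mo, 1 + t % 2, -9))
    for s in samples[3 * spec.n_trios :]:
        ped_rows.append((s, s, "0", "0", 0, -9))
    pedigree = pd.DataFrame(
        ped_rows, columns=["fid", "iid", "father", "mother", "sex", "phenotype"]
    )

    intervals = [(name, 0, length) for name, length in spec.contigs]
    return Cohort(spec, samples, sites, variants, genotypes, gvcfs, pedigree, intervals)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write gVCFs, PED, BED, and the truth genotype table; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample, records in cohort.gvcfs.items():
        p = outdir / f"{sample}.g.vcf"
        write_gvcf(p, sample, records, cohort.contigs)
        paths[f"gvcf:{sample}"] = p
    ped = outdir / "cohort.ped"
    cohort.pedigree.to_csv(ped, sep="\t", header=False, index=False)
    paths["pedigree"] = ped
    bed = outdir / "capture.bed"
    with open(bed, "w") as fh:
        for contig, start, end in cohort.intervals:
            fh.write(f"{contig}\t{start}\t{end}\n")
    paths["intervals"] = bed
    truth = outdir / "truth_genotypes.tsv"
    dose = pd.DataFrame(cohort.genotypes, columns=cohort.samples)
    table = pd.concat([cohort.variants.reset_index(drop=True), dose], axis=1)
    table.to_csv(truth, sep="\t", index=False)
    paths["truth"] = truth
    return paths


# ---------------------------------------------------------------------------
# GRM and phenotype inputs


def generate_grm(cohort: Cohort) -> Grm:
    """Family-block sparse GRM: 1 on the diagonal, 0.5 for parent-offspring."""
    n = len(cohort.samples)
    mat = sp.lil_matrix((n, n))
    mat.setdiag(1.0)
    for t in range(cohort.spec.n_trios):
        fa, mo, ch = 3 * t, 3 * t + 1, 3 * t + 2
        mat[fa, ch] = mat[ch, fa] = 0.5
        mat[mo, ch] = mat[ch, mo] = 0.5
    return Grm(list(cohort.samples), mat.tocsr())


def generate_phenotype_inputs(
    grm: Grm,
    n_pheno: int,
    heritabilities: Sequence[float],
    prevalences: Sequence[float],
    seed: int,
):
    """Simulate GRM-correlated random phenotypes (see assoc calibration).

    ``n_pheno`` continuous columns cycle through ``heritabilities``; each
    prevalence adds one binary column at heritability 1. Returns a
    PhenotypeMatrix with per-column metadata (trait type, h2, prevalence).
    """
    from .calibration import simulate_random_phenotypes

    return simulate_random_phenotypes(grm, n_pheno, heritabilities, prevalences, seed)


# ---------------------------------------------------------------------------
# annotations, site statistics, coverage


def generate_annotations(
    cohort: Cohort,
    n_genes: int,
    seed: int,
    class_probs: Sequence[float] = DEFAULT_CLASS_PROBS,
) -> pd.DataFrame:
    """Assign each observed variant to one gene and one functional class.

    Allele frequencies are empirical (alternate count over 2n chromosomes)
    from the truth genotype matrix; variants nobody carries are dropped.
    Genes are contiguous positional blocks, emulating exome gene structure.
    """
    if n_genes <= 0:
        raise ValueError(f"n_genes must be positive, got {n_genes}")
    if not np.isclose(sum(class_probs), 1.0):
        raise ValueError("class_probs must sum to 1")
    rng = np.random.default_rng(seed)
    af = cohort.empirical_af()
    carried = af > 0
    table = cohort.variants.loc[carried, ["key", "contig", "pos"]].reset_index(drop=True)
    table["af"] = af[carried]
    n_var = len(table)
    gene_of = np.minimum(
        (np.arange(n_var) * n_genes) // max(n_var, 1), n_genes - 1
    )
    table["gene"] = [f"GENE{g:04d}" for g in gene_of]
    table["functional_class"] = rng.choice(
        FUNCTIONAL_CLASSES, size=n_var, p=list(class_probs)
    )
    table["mean_coverage"] = np.clip(
        rng.normal(cohort.spec.mean_depth, 2.0, size=n_var), 1.0, None
    )
    return table[["key", "gene", "functional_class", "af", "mean_coverage", "contig", "pos"]]


def generate_site_stats(
    cohort: Cohort, seed: int, artifact_fraction: float = 0.08
) -> pd.DataFrame:
    """Per-variant site statistics for variant QC.

    Quality-by-depth is computed from the cohort's own gVCF records (sum of
    carriers' homozygous-reference likelihoods over their summed depth);
    strand-bias (FS) and mapping quality (MQ) have no read-level counterpart
    in the generative model, so they are synthesized, with a configurable
    fraction of sites given artifact-like values that fail the hard filters.
    """
    rng = np.random.default_rng(seed)
    pl0_sum: dict[tuple[str, int], float] = {}
    dp_sum: dict[tuple[str, int], float] = {}
    for records in cohort.gvcfs.values():
        for rec in records:
            if rec.is_block:
                continue
            key = (rec.contig, rec.pos)
            pl0_sum[key] = pl0_sum.get(key, 0.0) + rec.pl[0]
            dp_sum[key] = dp_sum.get(key, 0.0) + rec.dp

    af = cohort.empirical_af()
    carried = af > 0
    table = cohort.variants.loc[carried].reset_index(drop=True)
    site_keys = list(zip(table["contig"], table["pos"]))
    qd = np.array(
        [
            pl0_sum.get(k, 0.0) / dp_sum[k] if dp_sum.get(k, 0.0) > 0 else 0.0
            for k in site_keys
        ]
    )
    n = len(table)
    fs = rng.exponential(3.0, size=n)
    mq = np.clip(rng.normal(60.0, 2.5, size=n), 0, None)
    is_artifact = rng.random(n) < artifact_fraction
    bad_mode = rng.integers(0, 3, size=n)  # which statistic the artifact degrades
    fs = np.where(is_artifact & (bad_mode == 0), 61.0 + rng.exponential(30.0, size=n), fs)
    mq = np.where(is_artifact & (bad_mode == 1), rng.uniform(5.0, 29.5, size=n), mq)
    qd = np.where(is_artifact & (bad_mode == 2), rng.uniform(0.0, 1.9, size=n), qd)

    n_alts_at_site = cohort.variants.groupby(["contig", "pos"])["alt"].transform("count")
    n_alleles = (n_alts_at_site[carried].to_numpy() + 1).astype(int)
    is_indel = (table["alt"].str.len() != table["ref"].str.len()).to_numpy()
    site_tbl = cohort.variants.assign(is_indel=cohort.variants["alt"].str.len() != cohort.variants["ref"].str.len())
    mixed = (
        site_tbl.groupby(["contig", "pos"])["is_indel"].transform("nunique")[carried]
        .to_numpy()
        > 1
    )

    out = pd.DataFrame(
        {
            "key": table["key"],
            "allele_type": np.where(is_indel, "indel", "snv"),
            "n_alleles": n_alleles,
            "mixed": mixed,
            "spanning_deletion": False,
            "qd": qd,
            "fs": fs,
            "mq": mq,
            "read_pos_ranksum": np.nan,
            "mq_ranksum": np.nan,
        }
    )
    return out


def generate_coverage_matrix(
    intervals: Sequence[tuple[str, int, int]],
    samples: Sequence[str],
    mean_depth: float,
    seed: int,
    low_coverage_fraction: float = 0.0,
) -> pd.DataFrame:
    """Interval-by-sample mean coverage (rows = intervals, columns = samples)."""
    rng = np.random.default_rng(seed)
    index = [f"{c}:{s}-{e}" for c, s, e in intervals]
    cov = rng.normal(mean_depth, 4.0, size=(len(intervals), len(samples)))
    if low_coverage_fraction > 0:
        low = rng.random(len(intervals)) < low_coverage_fraction
        cov[low] = rng.uniform(2.0, 15.0, size=(int(low.sum()), len(samples)))
    return pd.DataFrame(np.clip(cov, 0.1, None), index=index, columns=list(samples))


def generate_kinship_table(cohort: Cohort, mean_depths: pd.Series | None = None) -> pd.DataFrame:
    """Pairwise kinship rows for related pairs (trio members), PLINK-style.

    Parent-offspring kinship is 0.25, i.e. above the pruning threshold 0.1.
    """
    rows = []
    for t in range(cohort.spec.n_trios):
        fa, mo, ch = (
            cohort.samples[3 * t],
            cohort.samples[3 * t + 1],
            cohort.samples[3 * t + 2],
        )
        rows.append((fa, ch, 0.25))
        rows.append((mo, ch, 0.25))
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "kinship"])
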