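# svcrkit

Desk-scale machinery for biobank-style exome association resources: a
**sparse, lossless joint-calling representation** for cohorts of gVCFs, the
**genotype/variant/sample QC rulebook** used for large exome callsets,
**random-phenotype calibration** of association tests with empirical
significance thresholds and summary-statistic filtering, and
**frequency-matched gene-set enrichment** — all exercisable end to end on
synthetic cohorts.

## Who this is for

Statistical geneticists and pipeline engineers who want to study, test, or
teach the computational core of large-scale rare-variant association
resources without access to the (controlled) cohort data those resources
are built from. Every input — gVCFs with reference blocks, trios, sparse
relatedness matrices, functional annotations, phenotypes — is generated
synthetically with the statistical structure the procedures assume.

## The core ideas

**Sparse cohort representation.** A joint callset is a locus × sample
matrix that keeps each gVCF record verbatim: a row for every locus any
sample's gVCF defines (including monomorphic rows where reference blocks
begin), row alleles = the union of alternates seen in any sample, and an
entry only where a sample's own gVCF had a record. Entries carry **LA**
("local alleles"), a map from the sample's own allele indices to the row's
global allele list, with GT/AD/PL renamed **LGT/LAD/LPL** to signal local
indexing. Stored entries therefore total exactly Σ per-sample record
counts — storage is *linear* in samples, unlike a project VCF — and the
transformation is lossless from the GQ-binned gVCF onward (reference-block
GQ is compressed to the bands 0/10/20/30/40/50/60). Merging is an outer
join on loci that rewrites only LA; a hierarchical merge with branch
factor N builds a cohort of S samples in ⌈log_N S⌉ rounds (a million
samples in 3 rounds at the default N = 100). A *densification* pass carries
each sample's most recent reference block along the chromosome to fill
homozygous-reference calls at loci the block spans, yielding a conventional
joint matrix on the fly.

**QC rulebook.** Genotypes pass "adj" iff DP ≥ 10 (5 for haploid), GQ ≥ 20,
and every alternate allele of a heterozygote carries > 0.2 of the allelic
depth. Sites are excluded for excess heterozygosity (inbreeding coefficient
F = 1 − obs/exp het < −0.3) or when no sample has an adj-pass non-reference
genotype; a random forest trained on transmitted/sibling singletons and
concordant array variants (true positives) versus hard-filter failures
(QD < 2, FS > 60, MQ < 30; class-balanced by downsampling) scores the rest
at the cutoffs 0.061 (SNVs) / 0.064 (indels). Samples pass interval QC
(85% of samples at ≥ 20× over 50 bp-padded capture intervals), sex-karyotype
bands on normalized X/Y ploidy, call-rate ≥ 0.99 and coverage ≥ 20×
filters, stratified 4-MAD outlier flags, and greedy
maximal-independent-set pruning of pairs with kinship > 0.1.

**Calibration.** Null phenotypes y = √h²·g + √(1−h²)·ε with
g ~ MVN(0, GRM) are simulated at a range of heritabilities (binary traits
by empirical-quantile thresholding at the requested prevalence). Score
tests (single-variant and rare-variant burden with MAF ≤ 0.01, ≥ 2 variants
per group) on these phenotypes give per-phenotype λ_GC
(median χ² / 0.4549) and the *empirical threshold rule*: the median across
null phenotypes of each phenotype's minimum p, p̃, estimates 1/(effective
tests), and 0.05 × p̃ is the per-phenotype significance threshold (0.05
expected false positives). Summary statistics are retained only with SE ≠ 0,
expected allele count (CAF × n_cases) ≥ 50, gene coverage ≥ 20 and
synonymous-class λ ≥ 0.75, and phenotype λ ≥ 0.75; correlated phenotypes
(r² > 0.5) are pruned preferring more cases.

**Enrichment and power.** Whether a gene set is unusually associated is
tested against 1,000 resampled background sets matched on cumulative allele
frequency (equal-width 0.01 bins), with smoothed empirical p, Fisher exact
p, sample odds ratio, and Wilson CIs. Power arithmetic uses the additive
variance explained 2pqa² and inverts the noncentral χ² tail for the minimum
detectable variance at a given level, power, and n.

## Worked example

```bash
python examples/01_sparse_cohort_roundtrip.py
```

prints, for an 8-sample synthetic cohort:

```
samples merged : 8 (branch factor 3, 2 rounds)
matrix rows    : 165 (loci seen in any sample)
stored entries : 200 (= sum of per-sample record counts 200; sparsity means storage is linear in input records)
variant rows   : 13 after densification
filled hom-ref : 77 calls carried forward from spanning reference blocks
joint VCF size : 21 lines
round trip     : byte-identical for all samples -> True
```

The entry-count equality is the linear-storage guarantee (merging never
densifies the matrix); the final flag is the losslessness guarantee (each
sample's binned gVCF is recovered byte-identically from the merged object).
The other examples walk the QC rulebook (`02`), the random-phenotype
threshold rule — e.g. a published group-test median minimum p of 5 × 10⁻⁶
maps to the threshold 2.5 × 10⁻⁷ (`03`) — and matched enrichment plus
minimum detectable variance (`04`).

A full synthetic pipeline (generate → convert/merge/densify → QC →
associate → calibrate → enrich) with a checksummed manifest and per-rule
attrition audit:

```bash
svcrkit pipeline run --outdir pipeline_out --seed 1
```

Other CLI verbs: `svcrkit svcr convert|merge|densify|export-pvcf|roundtrip-check`,
`svcrkit pipeline validate`, `svcrkit calib lambda|thresholds`,
`svcrkit power min-varexp`.

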