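# Methods

This note documents the models, conventions, and numerical choices behind
`svcrkit`, what the synthetic-data generator does and does not emulate, and
the known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sparse cohort representation

### Data model

The joint-calling object is a locus-sorted sequence of rows over an ordered
sample list. A row holds the locus, the reference allele string, and the
ordered alternates discovered in *any* sample at that locus; monomorphic
rows (reference base only) are materialized wherever a reference block
begins, so row cardinality exceeds that of a project VCF at small n and
converges toward it as rare variants accumulate. An entry exists for
(row, sample) iff that sample's gVCF had a record at that locus and is one
of:

- **reference block** — GQ band, minimum depth, END (0-based exclusive);
- **variant call** — LA (local→global allele index map, LA[0] = 0, strictly
  increasing when input alternates are emitted in collation order), LGT,
  LAD, LPL in local index space, GQ, DP.

Coordinates are 0-based half-open internally and 1-based inclusive in VCF
text, so the integer written for END equals the internal half-open end.
Ploidy is diploid on autosomes; haploid entries (|LGT| = 1) are supported
and LPL length follows ploidy via the standard VCF genotype-index formula
(implemented for arbitrary ploidy; only 1 and 2 are generated).

### GQ binning and losslessness

Reference blocks are compressed to the seven GQ bands
{0, 10, 20, 30, 40, 50, 60} — each GQ maps to the largest band at or below
it, capped at 60 — and adjacent same-band blocks are coalesced, keeping the
minimum depth. Losslessness is defined *from the binned, block-merged file
onward*: per-position original GQ inside a block is deliberately not
retained. The round-trip guarantee (convert → merge arbitrarily → restore a
sample's records) is exact on the modeled field set (CHROM, POS, REF, ALT,
END, GT, AD, PL, GQ, DP, MIN_DP) and is asserted byte-identically on
rendered text in the tests.

### Merge semantics

Merging is an outer join on loci. Merged alternates are the set union
sorted by a deterministic collation: plain lexicographic over concrete
alleles, with symbolic alleles (`*`, `<NON_REF>`) ordered last (among
themselves also lexicographically). Only the LA field of surviving entries
is rewritten; LGT/LAD/LPL are untouched because they index *positions of
LA*, not global alleles. Consequences, all property-tested:

- stored entry count is invariant under merging (linear storage);
- any bracketing of merges yields an identical object (associativity), so
  the hierarchical merge (rounds of `branch_factor` inputs, default 100)
  equals one flat merge while executing ⌈log_N S⌉ rounds;
- all inputs at a locus must agree on the reference string — a genuine
  REF conflict (e.g. overlapping deletions trimmed differently) is an
  error rather than silently renormalized. The synthetic generator derives
  the reference base deterministically from (contig, position), so
  conflicts cannot arise in generated cohorts.

### Densification

A forward scan per contig keeps, per sample, the most recent reference
block. At each requested row (default: rows with ≥ 1 concrete alternate), a
defined variant entry is converted to global indices through LA — LAD
expands with zeros for alleles the sample never observed, LPL positions for
genotypes involving unobserved alleles are left missing — and an undefined
entry becomes a homozygous-reference call (with the block's GQ band and
min-DP) iff the carried block's END spans the row position; otherwise the
call is missing. No state crosses contigs. The densified matrix can be
exported as a multi-sample VCF; the symbolic `<NON_REF>` alternate is kept
in the export so a parse-back reproduces the matrix exactly (a conventional
project VCF would drop it; the exporter is a convenience target, not a
contribution).

## Synthetic cohorts

The generator produces, from one seed: per-sample gVCFs, a 6-column
pedigree, truth genotypes, capture intervals, sparse GRM, kinship pairs,
annotations, site statistics, and coverage matrices. The model:

- **Sites**: per-contig count ~ Binomial(length, variant_rate
  (default 0.02)); positions uniform without replacement; 5% of sites get a
  second alternate; alternates are SNVs or short insertions (15%) — REF is
  always a single base, so spanning deletions (`*`) never arise in
  generated data (the merge collation and the spanning-deletion flag
  nevertheless support them and are unit-tested directly).
- **Frequencies**: true alternate frequencies ~ Beta(0.15, 4) by default —
  rare-skewed with a common tail, qualitatively matching an exome cohort;
  no population-genetic model is claimed, and the frequency-spectrum test
  compares *drawn* frequencies to the requested Beta (empirical cohort
  frequencies at small n are binomially discretized and cannot match a
  continuous law).
- **Genotypes**: founders are Hardy-Weinberg draws; trio offspring receive
  one uniformly chosen allele from each parent, each transmission mutated
  with probability `denovo_rate` (default 0). With rate 0, Mendelian
  consistency is exact by construction and verified against an exhaustive
  trio oracle.
- **Reads**: depth ~ Poisson(mean_depth, default 30×); allelic depths
  multinomial under a symmetric per-read error model (error 10⁻³); PLs are
  the phred-scaled, min-normalized multinomial likelihoods over all local
  genotypes (including `<NON_REF>` as a zero-support allele); GQ is the
  second-smallest PL capped at 99. Reference blocks get raw GQ ~
  N(55, 18²) clipped to [0, 99] and random lengths of 30–300 bp, so
  binning and block coalescing are both exercised.
- **Site statistics**: quality-by-depth is *computed* from the cohort's own
  records as Σ carriers' hom-ref PL over Σ carrier depth (the verbal
  definition adopted here; it differs from the QUAL/DP convention of
  common callers, and which one the emulated pipeline truly used is not
  decidable from its description — flagged as a known ambiguity).
  Strand-bias (FS) and mapping quality (MQ) have no read-level counterpart
  in this model and are synthesized (FS ~ Exp(3), MQ ~ N(60, 2.5)), with a
  configurable artifact fraction (default 8%) given a failing FS, MQ, or QD
  value; rank-sum features are emitted missing and imputed with a
  missingness indicator for the forest. Array concordance is synthesized as
  0.99 for clean variants and 0.5 for artifact sites.
- **GRM**: block-diagonal family structure (diagonal 1, parent-offspring
  0.5), stored sparse; positive semi-definiteness is validated by attempted
  Cholesky factorization with 10⁻⁸ diagonal jitter.

What passing tests on these cohorts show: the *procedures* behave as
specified (losslessness, linear storage, calibration, threshold rules,
matched resampling). What they do not show: robustness to alignment
artifacts, sequence-context error, population structure, batch effects, or
any biological signal — none of which the generator emulates.

## QC rulebook

Thresholds are module constants, configuration defaults, and
boundary-tested: adj genotype filter DP ≥ 10 (5 haploid) / GQ ≥ 20 / per-alt
heterozygote balance > 0.2 (fraction of summed AD; the denominator for
multi-allelic heterozygotes is the genotype's total AD, an explicit
convention since only "minor allele balance" is specified); inbreeding
coefficient F = 1 − obs/exp heterozygotes with exclusion at F < −0.3 and F
undefined (site unflagged) when expected heterozygosity is 0; hard-filter
false-positive labels at QD < 2 ∨ FS > 60 ∨ MQ < 30; RF true-positive
probability cutoffs 0.061 (SNV) / 0.064 (indel) plus the two hard
exclusions (F, no adj-pass carrier). The allele-balance feature is the
maximum across heterozygotes of the exact two-sided binomial p at 0.5,
two-sided by summing outcomes no more probable than observed. Training
classes are balanced by seeded downsampling without replacement of the
larger class (the specification describes only downsampling false
positives; when false positives are the scarcer class the same rule is
applied in reverse so balance always holds).

Sample QC: interval screen passes intervals (padded 50 bp, merged when
overlapping after padding; a merged interval's per-sample coverage is the
length-weighted mean of its members) where ≥ 85% of samples average ≥ 20×,
both boundaries inclusive. Sex karyotypes come from ploidy bands (X: ≤1.55
single, 1.6–2.15 double, ≥2.2 triple; Y: <0.06 none, 0.06–1.3 single, ≥1.4
double); band gaps are `ambiguous`, which fails the hard filters together
with call rate < 0.99 or coverage < 20×. Outlier flags use the *unscaled*
MAD (no 1.4826 consistency factor — a literal reading, documented so
results are interpretable) at 4 MADs within population × batch strata;
zero-MAD metrics flag nothing. Related samples (kinship > 0.1) are pruned
by a greedy maximal independent set: repeatedly remove the highest-degree
vertex, ties broken by lower priority (mean depth) then smaller id, then
re-add any removed vertex with no kept neighbor (highest priority first) so
the result is maximal as well as independent. The greedy is deliberate —
the exact maximum problem is NP-hard and the emulated tool is greedy; exact
enumeration serves only as a test oracle on small graphs.

## Association calibration

Phenotype simulation uses y = √h²·g + √(1−h²)·ε, g = Lz with LLᵀ = GRM
(Cholesky with 10⁻⁸ jitter), ε i.i.d. standard normal. Binary traits
threshold the liability at the empirical (1 − prevalence) quantile so case
counts are exactly ⌊πn⌋ — an O(1/n) deviation from the normal quantile that
makes the prevalence invariant exactly testable.

The association tests are score tests from linear/logistic null models with
covariates, vectorized over variants — deliberately lightweight plumbing
that exercises every downstream filter; mixed-model group machinery is not
reimplemented, and externally computed group-test records can be ingested
alongside. Burden scores sum minor-allele counts over group variants with
MAF ≤ 0.01, requiring ≥ 2 qualifying variants. λ_GC transforms two-sided p
through the χ²₁ quantile function and divides the median by 0.4549. The
empirical threshold rule reports (1/p̃, 0.05·p̃) for p̃ the median of
per-phenotype minimum p; the rule applied to a published burden median of
1.3 × 10⁻⁵ yields 6.5 × 10⁻⁷ where 6.7 × 10⁻⁷ was printed alongside — the
printed median is evidently rounded, and no reconciliation is attempted.
The summary-statistic gate is a pure filter over precomputed inputs
(per-gene synonymous λ, per-phenotype λ, gene coverage, expected allele
count CAF × n_cases — n_defined for continuous traits, adopted as stated),
which makes idempotence structural. Phenotype pruning standardizes columns
(missing values mean-imputed *only* for the correlation step; tests drop
missing), links pairs with r² > 0.5, and keeps a maximal independent set
preferring more cases.

## Matched enrichment and power

Targets and backgrounds are binned by cumulative allele frequency into
half-open width-0.01 bins; an optional `top_bin_edge` collapses the sparse
tail into one open-ended bin (off by default). Each of n_sets (default
1,000) resamples draws, per target unit, a background unit from the same
bin with replacement, recording the proportion with ≥ 1 association and the
mean association count. Empirical p uses (r + 1)/(n + 1) smoothing to avoid
zero from finite resampling, and is reported for both statistics: the
proportion (the headline quantity) and the mean count. The proportion takes
only n_target + 1 values, so its smoothed p is discrete and lumpy; the mean
count has a near-continuous null, and calibration checks (uniform p under
uniformly drawn targets) use it for that reason. The 2×2 comparison reports
the sample (cross-product) odds ratio — the estimator behind any published
value being unstated, the choice is documented and deliberate — plus
Fisher's exact p and Wilson 95% CIs. The engine is one procedure with
(target, background, frequency key) instances: gene sets, deleteriousness
bins of missense variants, and clinical-pathogenicity classes all reduce to
it.

Power: variance explained of a purely additive biallelic variant is
2pqa²; a 1-df chi-square test has noncentrality n × (variance explained),
so the minimum detectable variance at level α and target power is found by
bisection on the noncentral tail (tolerance 10⁻¹²; strictly decreasing in n
and α, increasing in power; halving n exactly doubles the result). The
power behind any published minimum-variance figure is unstated, so the
operation exposes power as a parameter; at n = 394,841 and α = 2.5 × 10⁻⁷
the acceptance script reports the value at power 0.8 (≈ 0.009%), which is
below a published ballpark of 0.02% — consistent with that figure assuming
a stricter power or additional attrition, but not reproducible without the
assumption.

## Pipeline defaults and problem sizes

The end-to-end pipeline defaults to 120 samples (8 trios), two 6 kb
contigs at variant rate 0.02, 12 random phenotypes over heritabilities
{0.1, 0.2, 0.5, 1} plus one binary trait at prevalence 0.1, and 12 genes —
sizes chosen so that singleton MAF (1/2n ≈ 0.004) sits under the 0.01
group-test cap and burden tests actually form, while a full run stays in
seconds. Every QC threshold default equals the rulebook constant above and
is rejected by config validation when out of bounds; unknown keys are
errors; manifests carry SHA-256 checksums and are byte-reproducible under a
fixed seed. The expected-allele-count rule (≥ 50) is a biobank-scale power
filter: at 120 samples it removes essentially all records (visible in the
audit log), so the pipeline's enrichment stage falls back to pre-gate
records when fewer than four gene groups survive, and notes which input it
used. The acceptance script's stochastic checks use 2,000 × 2,000
null score tests, 20 round-trip cohorts of 12 samples × ~4 kb, a
1,000-sample miniature merge, and 200 enrichment calibration replicates of
60 targets against 340 backgrounds with 199 resamples each.

## Known limitations

- The generator has no read-level model: rank-sum features are absent
  (imputed missing), FS/MQ are synthesized, and the forest's separation of
  artifact sites rests on the synthetic feature distributions, not on
  sequencing physics.
- Multi-base reference alleles (deletions) are not generated, so REF-
  conflict handling at merge is tested only via hand-built cases.
- The QD definition follows the verbal likelihood-over-depth formulation;
  pipelines using QUAL/DP will produce systematically different values.
- Binary-trait score tests at very low prevalence inherit the usual
  small-count instability; the calibration checks use prevalences ≥ 0.1.
- λ-based gates assume enough records per gene/phenotype for a stable
  median; the desk-scale pipeline audit makes the attrition visible rather
  than hiding it.
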