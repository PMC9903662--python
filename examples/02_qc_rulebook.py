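"""Apply the genotype, variant, and sample QC rules to hand-built inputs.

Shows the adj genotype criteria at their boundaries, the excess-heterozygote
inbreeding coefficient, the site hard filters that label false positives,
sex-karyotype assignment from ploidy bands, and related-sample pruning.
"""

import pandas as pd

from svcrkit.sample_qc import (
    PloidyEstimate,
    impute_sex_karyotype,
    prune_related_samples,
    sample_hard_filters,
)
from svcrkit.variant_qc import (
    GenotypeObs,
    adj_filter,
    hard_filter_label,
    inbreeding_coefficient,
    max_ab_binomial_p,
)

print("== adj genotype filter (DP >= 10, GQ >= 20, het balance > 0.2) ==")
for desc, obs in [
    ("boundary het DP=10 GQ=20 AD=(5,5)", GenotypeObs(2, 10, 20, (0, 1), (5, 5))),
    ("hom-ref DP=9 GQ=99", GenotypeObs(2, 9, 99, (0, 0))),
    ("het with 10% allele balance", GenotypeObs(2, 10, 30, (0, 1), (9, 1))),
    ("haploid DP=5 GQ=20", GenotypeObs(1, 5, 20, (1,), (0, 5))),
]:
    ok, reason = adj_filter(obs)
    print(f"  {desc:38s} -> {'pass' if ok else 'FAIL (' + reason + ')'}")

print("\n== excess heterozygotes (flag when F < -0.3) ==")
all_het = [(0, 1)] * 100
print(f"  100/100 heterozygous at p=0.5 -> F = {inbreeding_coefficient(all_het):.2f}")
hwe = [(0, 0)] * 25 + [(0, 1)] * 50 + [(1, 1)] * 25
print(f"  exact Hardy-Weinberg counts   -> F = {inbreeding_coefficient(hwe):.2f}")

print("\n== site hard filters (FP labels: QD<2, FS>60, MQ<30) ==")
for qd, fs, mq in [(1.5, 0.0, 60.0), (30.0, 61.0, 60.0), (30.0, 0.0, 60.0)]:
    print(f"  QD={qd:5.1f} FS={fs:5.1f} MQ={mq:5.1f} -> "
          f"{'fail' if hard_filter_label(qd, fs, mq) else 'pass'}")

print("\n== allele-balance binomial feature ==")
print(f"  hets (10,0) and (6,4) -> max p = {max_ab_binomial_p([(10, 0), (6, 4)]):.4f}")

print("\n== sex karyotype from normalized ploidy ==")
for x, y in [(1.0, 1.0), (1.98, 0.01), (1.57, 0.02), (2.0, 1.0)]:
    k = impute_sex_karyotype(PloidyEstimate("s", x, y))
    ok, reasons = sample_hard_filters(k, 0.995, 30.0)
    print(f"  x={x:4.2f} y={y:4.2f} -> {k:9s} hard filters: "
          f"{'pass' if ok else 'fail (' + ','.join(reasons) + ')'}")

print("\n== relatedness pruning (kinship > 0.1, keep deeper sample) ==")
kin = pd.DataFrame(
    [("mother", "child", 0.25), ("father", "child", 0.25)],
    columns=["sample_i", "sample_j", "kinship"],
)
kept = prune_related_samples(
    kin, ["mother", "father", "child", "stranger"],
    {"mother": 31.0, "father": 29.0, "child": 24.0},
)
print(f"  trio + stranger -> kept: {sorted(kept)}")
print("  (the child links to both parents, so removing it alone resolves the family)")
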