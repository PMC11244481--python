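"""SNP consequence classification, impact rates and dominance classes.

Builds an mRNA with a known ORF, classifies substitutions and an
insertion, then computes genotype-group trait statistics: the impact rate
(High - Low)/Low x 100% and the seven-class dominance taxonomy of the
heterozygote relative to both homozygotes.
"""

import numpy as np

from ginfunnel.simulate import make_mrna_with_orf
from ginfunnel.snp_effect import (
    classify_genetic_effect,
    classify_mutation,
    find_orf,
    snp_trait_test,
)

rng = np.random.default_rng(11)
seq, orf_start, orf_end = make_mrna_with_orf(rng, total_len=600, utr5=100, orf_codons=120)
orf = find_orf(seq, min_len=150)
print(f"ORF found at {orf} (planted {orf_start}-{orf_end})")

pos = orf_start + 31  # second position of codon 11
ref = seq[pos - 1]
alt = next(b for b in "ACGT" if b != ref)
for label, r, a in [("substitution", ref, alt), ("1-bp insertion", ref, ref + "T")]:
    rec = classify_mutation("demo", seq, orf, pos, r, a)
    print(f"  {label:<15} {r}->{a} at mRNA pos {pos}: {rec.mclass}")

# genotype groups: favorable homozygote 0.72, het 0.40, other homozygote 0.55
g = np.array([0] * 40 + [1] * 30 + [2] * 40)
y = np.concatenate([
    rng.normal(0.72, 0.08, 40), rng.normal(0.40, 0.08, 30), rng.normal(0.55, 0.08, 40),
])
stat = snp_trait_test(g, y, snp_id="snp_demo", gene_id="demo")
print(f"homozygote contrast     : t = {stat.t:.2f}, p = {stat.p:.1e}, "
      f"impact rate = {stat.impact_rate:.1f}%")

eff = classify_genetic_effect(y[g == 0], y[g == 1], y[g == 2],
                              hom1_allele="A", hom2_allele="G")
print(f"favorable allele        : {eff.favorable_allele} "
      f"(means {eff.m_favorable:.2f} / {eff.m_het:.2f} / {eff.m_unfavorable:.2f})")
print(f"dominance class         : {eff.effect_class} "
      f"(het vs favorable hom p = {eff.het_vs_favorable_p:.1e})")
print()
print("A heterozygote mean below both homozygotes is a negative over-dominant")
print("(NOD) configuration - the pattern reported for the cloned gene's")
print("diagnostic SNP.")
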