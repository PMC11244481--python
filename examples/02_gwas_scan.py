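"""Single- and multi-locus genome-wide association on planted QTNs.

Simulates a 344-cultivar panel with two planted QTNs, runs the six
single-locus models (GLM variants and kinship mixed models) plus the
two-stage empirical-Bayes multi-locus scan, and reports what survives the
Bonferroni and LOD >= 3 thresholds.
"""

import numpy as np

from ginfunnel.gwas_multi import merge_loci, multilocus_scan
from ginfunnel.gwas_single import bonferroni_threshold, compute_kinship, run_six_models
from ginfunnel.simulate import SimConfig, simulate_genotypes, simulate_trait

cfg = SimConfig(seed=3, n_samples=344, n_snps=2000, n_chrom=8, n_subpops=2)
genotypes = simulate_genotypes(cfg)
traits, truth = simulate_trait(genotypes, cfg)
y = traits.sample_means().to_numpy()
print(f"planted QTNs            : {truth.qtn_snp_ids} "
      f"(beta = {[round(b, 3) for b in truth.qtn_betas]} mg/g per allele)")

p_thresh, neg_log10 = bonferroni_threshold(genotypes.n_snps, fwer=0.01)
print(f"Bonferroni threshold    : p = {p_thresh:.3g} (-log10 p = {neg_log10:.2f})")

per_model = run_six_models(genotypes, y)
for tag, res in per_model.items():
    hits = [r for r in res if r.p <= p_thresh]
    loci = merge_loci(hits, max_gap=20_000)
    best = min(res, key=lambda r: r.p)
    print(f"{tag:<9}: {len(hits):>2} significant SNPs -> {len(loci)} loci "
          f"(best {best.snp}, p = {best.p:.2e}, PVE = {best.pve:.2f})")

kin = compute_kinship(genotypes)
multi = multilocus_scan(genotypes, y, kin, lod_min=3.0)
print(f"multi-locus EB scan     : {len(multi)} markers at LOD >= 3: "
      f"{[(h.snp, round(h.lod, 1)) for h in multi]}")
print()
print("Every model should place its best hit on (or in LD with) a planted")
print("QTN; the mixed models keep the rest of the genome quiet despite the")
print("two-subpopulation structure.")
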