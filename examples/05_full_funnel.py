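"""The whole candidate-gene funnel end-to-end on a synthetic dataset.

Generates a coherent 344-cultivar world (genotypes with LD and structure,
replicated trait with two QTNs, expression with a trait-tracking module
placed inside the first QTN's window, gene models with ORFs), writes it in
standard formats, and runs every stage: BLUP -> six single-locus scans ->
multi-locus LOD scan -> QTN intersection -> gene windows -> co-expression
modules and hubs -> SNP effects -> enzyme-panel networks.
"""

import json

from ginfunnel.pipeline import RunConfig, run_pipeline
from ginfunnel.simulate import SimConfig

cfg = RunConfig(outdir="funnel_demo", simulate=True, seed=1)
sim = SimConfig(seed=1, n_samples=344, n_snps=2000, n_chrom=8, n_genes=800,
                snp_spacing_bp=2000, gene_length_bp=4500, gene_spacing_bp=5000)
report = run_pipeline(cfg, sim)

w, s, n = report["wgcna"], report["snp_effect"], report["network"]
print(f"QTNs (all single-locus AND all multi-locus): {report['funnel']['n_qtns']}")
print(f"candidate genes I  (±500 kb windows)       : {report['funnel']['n_candidates_1']}")
print(f"candidate genes II (key-module hubs)       : {len(w['hubs'])}  "
      f"[key module {w['key_module']}, trait r = {w['key_module_r']:.2f}]")
print(f"candidate genes III (significant SNPs)     : {len(s['candidates_3'])}")
print(f"confirmed candidates (p <= 0.05 network)   : {len(n.get('confirmed', []))}")
print(f"key candidates (p <= 1e-6 network)         : {n.get('key_candidates', [])}")
truth = json.load(open("funnel_demo/simulated_truth.json"))
planted = {g for g, m in truth["module_assignment"].items() if m == 0}
print(f"key candidates inside planted module       : "
      f"{sorted(set(n.get('key_candidates', [])) & planted)}")
print()
print("The narrowing mirrors the published funnel: hundreds of window genes")
print("collapse to a handful of hubs and finally to the gene(s) whose")
print("variants and co-expression both track the trait.")
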