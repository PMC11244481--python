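"""End-to-end orchestration of the candidate-gene funnel.

Stages: (optional) simulate -> blup -> gwas-single -> gwas-multi -> funnel
-> wgcna -> snp-effect -> network -> effects.  Each stage writes TSV
outputs plus a JSON manifest (input hashes, parameters, seed, package
version) into the output directory, and the stage-by-stage narrowing of
the candidate set is logged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, data_io, simulate as sim
from .blup import fit_blup, ks_normality
from .funnel import candidate_gene_ids, genes_in_windows, intersect_models, QTN
from .gwas_multi import merge_loci, multilocus_scan
from .gwas_single import (
    AssocResult,
    bonferroni_threshold,
    compute_kinship,
    ld_prune,
    results_to_frame,
    run_six_models,
)
from .network import call_candidates, group_network_comparison
from .snp_effect import (
    classify_genetic_effect,
    classify_mutation,
    find_orf,
    significant_snp_summary,
    snp_trait_test,
)
from .wgcna import (
    adjacency_matrix,
    detect_modules,
    filter_expression,
    key_module,
    module_trait,
    pick_soft_threshold,
    remove_outlier_samples,
    select_hubs,
    tom_matrix,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of a funnel run (paths + stage thresholds)."""

    vcf: str | None = None
    gff3: str | None = None
    fasta: str | None = None
    expression: str | None = None
    traits: str | None = None
    outdir: str = "ginfunnel_out"
    # stage parameters
    fwer: float = 0.01
    q_pcs: int = 3
    prune_window: int = 50
    prune_step: int = 50
    prune_r2: float = 0.2
    stage1_p: float = 0.01
    lod_min: float = 3.0
    merge_gap: int = 20_000
    flank: int = 500_000
    zero_fraction: float = 0.70
    # soft-threshold power; None selects automatically from the scale-free
    # fit, the default mirrors the conventional visually-chosen value
    power: float | None = 8.5
    r2_target: float = 0.85
    weight_min: float = 0.4
    top_k: int = 5
    alpha: float = 0.05
    p_key: float = 1e-6
    group_size: int = 14
    orf_min_len: int = 150
    seed: int = 0
    simulate: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _hash_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _manifest(outdir: Path, stage: str, config: RunConfig, inputs: dict[str, str], extra: dict) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "input_hashes": inputs,
        **extra,
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2, default=str))


def write_simulated_inputs(config: RunConfig, sim_config: sim.SimConfig | None = None) -> RunConfig:
    """Generate a synthetic dataset and write it in the standard formats;
    returns a copy of the run config pointing at the written files."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if sim_config is None:
        sim_config = sim.SimConfig(seed=config.seed)
    ds = sim.simulate_dataset(sim_config)
    paths = {
        "vcf": outdir / "simulated.vcf",
        "gff3": outdir / "simulated.gff3",
        "fasta": outdir / "simulated_mrna.fasta",
        "expression": outdir / "simulated_expression.tsv",
        "traits": outdir / "simulated_traits.tsv",
    }
    data_io.write_vcf(ds.genotypes, paths["vcf"])
    data_io.write_gff_genes(ds.gene_models, paths["gff3"])
    data_io.write_fasta(ds.fasta, paths["fasta"])
    data_io.write_expression(ds.expression, paths["expression"])
    data_io.write_traits(ds.traits, paths["traits"])
    (outdir / "simulated_truth.json").write_text(json.dumps(ds.truth.to_json_dict(), indent=2))
    return dataclasses.replace(
        config,
        vcf=str(paths["vcf"]), gff3=str(paths["gff3"]), fasta=str(paths["fasta"]),
        expression=str(paths["expression"]), traits=str(paths["traits"]),
    )


def run_pipeline(config: RunConfig, sim_config: sim.SimConfig | None = None) -> dict:
    """Execute the whole funnel; returns a run report dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.simulate:
        config = write_simulated_inputs(config, sim_config)
    for key in ("vcf", "gff3", "fasta", "expression", "traits"):
        path = getattr(config, key)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"input {key!r} missing: {path}")
    inputs = {k: _hash_file(getattr(config, k)) for k in ("vcf", "gff3", "fasta", "expression", "traits")}
    report: dict = {"outdir": str(outdir)}

    # --- stage: blup -------------------------------------------------------
    traits = data_io.read_traits(config.traits)
    blup_res = fit_blup(traits)
    d_stat, ks_p = ks_normality(blup_res.blup.to_numpy())
    blup_df = blup_res.blup.rename("blup").reset_index()
    data_io.write_table(blup_df, outdir / "blup.tsv")
    (outdir / "blup_varcomp.json").write_text(json.dumps({
        **blup_res.variance_components, "mu": blup_res.mu,
        "converged": blup_res.converged, "ks_D": d_stat, "ks_p": ks_p,
    }, indent=2))
    _manifest(outdir, "blup", config, inputs, {"n_samples": len(blup_res.blup)})
    report["blup"] = {"ks_p": ks_p, **blup_res.variance_components}

    # --- stage: gwas-single ------------------------------------------------
    gm = data_io.read_vcf(config.vcf)
    y = blup_res.blup.reindex(gm.samples).to_numpy()
    if np.isnan(y).any():
        raise ValueError("trait table lacks measurements for some VCF samples")
    pruned_ids = ld_prune(gm, config.prune_window, config.prune_step, config.prune_r2)
    pd.DataFrame({"snp": pruned_ids}).to_csv(outdir / "pruned_snps.tsv", sep="\t", index=False)
    per_model = run_six_models(gm, y, q_structure=config.q_pcs, q_pca=config.q_pcs)
    p_thresh, neg_log10 = bonferroni_threshold(gm.n_snps, config.fwer)
    single_frames = []
    single_loci = {}
    for tag, res in per_model.items():
        df = results_to_frame(res)
        single_frames.append(df)
        hits = [r for r in res if r.p <= p_thresh and not r.flagged]
        single_loci[tag] = merge_loci(hits, max_gap=config.merge_gap, score_attr="lod")
    data_io.write_table(pd.concat(single_frames), outdir / "gwas_single.tsv")
    _manifest(outdir, "gwas_single", config, inputs, {
        "bonferroni_p": p_thresh, "neg_log10": neg_log10,
        "hits_per_model": {t: sum(len(l.members) for l in ls) for t, ls in single_loci.items()},
    })
    report["gwas_single"] = {"bonferroni_p": p_thresh, "neg_log10": neg_log10,
                             "loci_per_model": {t: len(l) for t, l in single_loci.items()}}

    # --- stage: gwas-multi -------------------------------------------------
    kin = compute_kinship(gm)
    multi_presets = {"EB_A": config.stage1_p, "EB_B": 0.02, "EB_C": 0.005}
    multi_loci = {}
    multi_rows = []
    for tag, s1p in multi_presets.items():
        hits = multilocus_scan(gm, y, kin, stage1_p=s1p, lod_min=config.lod_min)
        multi_loci[tag] = merge_loci(hits, max_gap=config.merge_gap, score_attr="lod")
        for h in hits:
            multi_rows.append((tag, h.snp, h.chrom, h.pos, h.effect, h.lod, h.pve))
    data_io.write_table(
        pd.DataFrame(multi_rows, columns=["model", "snp", "chrom", "pos", "effect", "lod", "pve"]),
        outdir / "gwas_multi.tsv",
    )
    _manifest(outdir, "gwas_multi", config, inputs,
              {"loci_per_model": {t: len(l) for t, l in multi_loci.items()}})
    report["gwas_multi"] = {"loci_per_model": {t: len(l) for t, l in multi_loci.items()}}

    # --- stage: funnel -----------------------------------------------------
    per_model_loci = {**single_loci, **multi_loci}
    required = [set(single_loci), set(multi_loci)]
    qtns = intersect_models(per_model_loci, required, max_gap=config.merge_gap)
    genes = data_io.read_gff_genes(config.gff3)
    windows = genes_in_windows(qtns, genes, flank=config.flank)
    candidates1 = candidate_gene_ids(windows)
    data_io.write_table(
        pd.DataFrame([(q.chrom, q.pos, ";".join(q.supporting_models), q.best_score) for q in qtns],
                     columns=["chrom", "pos", "models", "best_score"]),
        outdir / "qtns.tsv",
    )
    data_io.write_table(windows, outdir / "candidate_genes_1.tsv")
    _manifest(outdir, "funnel", config, inputs, {"n_qtns": len(qtns), "n_candidates_1": len(candidates1)})
    report["funnel"] = {"n_qtns": len(qtns), "n_candidates_1": len(candidates1)}
    log.info("funnel: %d QTNs -> %d candidate genes I", len(qtns), len(candidates1))

    # --- stage: wgcna ------------------------------------------------------
    expr = data_io.read_expression(config.expression)
    enzyme_ids = [g for g in expr.genes if g.startswith("enzyme")]
    cand_expr = expr.subset_genes([g for g in candidates1 if g in set(expr.genes)])
    report["wgcna"] = {}
    hubs: list[str] = []
    if cand_expr.n_genes >= 3:
        filtered = filter_expression(cand_expr, config.zero_fraction)
        filtered, dropped = remove_outlier_samples(filtered)
        soft = pick_soft_threshold(filtered, r2_target=config.r2_target)
        power_used = config.power if config.power is not None else soft.chosen_power
        adj = adjacency_matrix(filtered, power_used)
        tom = tom_matrix(adj)
        modules = detect_modules(tom, filtered.genes)
        trait_vec = blup_res.blup.reindex(filtered.samples).to_numpy()
        modules = module_trait(modules, filtered, trait_vec)
        key = key_module(modules)
        hubs = select_hubs(key, adj, filtered.genes, config.weight_min, config.top_k)
        data_io.write_table(
            pd.DataFrame(
                [(m.color, g, m.trait_r, m.trait_p) for m in modules for g in m.genes],
                columns=["module", "gene", "trait_r", "trait_p"],
            ),
            outdir / "modules.tsv",
        )
        pd.DataFrame({"hub": hubs}).to_csv(outdir / "hubs.tsv", sep="\t", index=False)
        report["wgcna"] = {
            "n_filtered_genes": filtered.n_genes, "dropped_samples": dropped,
            "chosen_power": power_used, "fit_selected_power": soft.chosen_power,
            "n_modules": sum(m.color != "grey" for m in modules),
            "key_module": key.color, "key_module_r": key.trait_r, "hubs": hubs,
        }
    _manifest(outdir, "wgcna", config, inputs, report["wgcna"])
    log.info("wgcna: %d candidates II (hubs)", len(hubs))

    # --- stage: snp-effect -------------------------------------------------
    fasta = data_io.read_fasta(config.fasta)
    gene_by_id = {g.id: g for g in genes}
    stats_rows = []
    mut_records = []
    snp_stats = []
    effect_rows = []
    y_series = blup_res.blup
    for gid in hubs:
        gmodel = gene_by_id.get(gid)
        if gmodel is None or gid not in fasta:
            continue
        seq = fasta[gid]
        orf = find_orf(seq, min_len=config.orf_min_len)
        for j, snprec in enumerate(gm.snps):
            if snprec.chrom != gmodel.chrom or not (gmodel.start <= snprec.pos <= gmodel.end):
                continue
            calls = gm.calls[:, j]
            stat = snp_trait_test(calls, y_series.reindex(gm.samples).to_numpy(), snprec.id, gid)
            snp_stats.append(stat)
            pos_in_mrna = snprec.pos - gmodel.start + 1
            try:
                rec = classify_mutation(gid, seq, orf, pos_in_mrna, snprec.ref, snprec.alt)
            except ValueError:
                continue
            mut_records.append(rec)
            stats_rows.append((snprec.id, gid, stat.mean_high, stat.mean_low, stat.t, stat.p,
                               stat.impact_rate, rec.mclass))
            has_three = all((calls == c).sum() > 0 for c in (0, 1, 2))
            if has_three and stat.testable and stat.p <= config.alpha:
                yv = y_series.reindex(gm.samples).to_numpy()
                eff = classify_genetic_effect(yv[calls == 0], yv[calls == 1], yv[calls == 2],
                                              hom1_allele=snprec.ref, hom2_allele=snprec.alt)
                effect_rows.append((snprec.id, gid, eff.favorable_allele, eff.effect_class,
                                    eff.m_favorable, eff.m_het, eff.m_unfavorable,
                                    eff.het_vs_favorable_p))
    summary = significant_snp_summary(snp_stats, alpha=config.alpha, mutations=mut_records)
    sig_by_gene = {
        gid: any(s.testable and s.p <= config.alpha for s in snp_stats if s.gene == gid)
        for gid in hubs
    }
    candidates3 = [g for g, ok in sig_by_gene.items() if ok]
    data_io.write_table(
        pd.DataFrame(stats_rows, columns=["snp", "gene", "mean_high", "mean_low", "t", "p",
                                          "impact_rate", "mutation_class"]),
        outdir / "snp_effects.tsv",
    )
    data_io.write_table(
        pd.DataFrame(effect_rows, columns=["snp", "gene", "favorable_allele", "effect_class",
                                           "m_favorable", "m_het", "m_unfavorable", "p"]),
        outdir / "genetic_effects.tsv",
    )
    _manifest(outdir, "snp_effect", config, inputs, {"summary": summary, "n_candidates_3": len(candidates3)})
    report["snp_effect"] = {"summary": summary, "candidates_3": candidates3}
    log.info("snp-effect: %d candidates III", len(candidates3))

    # --- stage: network ----------------------------------------------------
    report["network"] = {}
    if candidates3 and enzyme_ids:
        confirmed, key_cands, nets = call_candidates(
            expr, candidates3, enzyme_ids, p_confirm=config.alpha, p_key=config.p_key,
        )
        nets[config.alpha].edge_table().to_csv(outdir / "network_p05_edges.tsv", sep="\t", index=False)
        nets[config.p_key].edge_table().to_csv(outdir / "network_key_edges.tsv", sep="\t", index=False)
        report["network"] = {
            "confirmed": confirmed, "key_candidates": key_cands,
            "n_nodes_p05": nets[config.alpha].n_nodes, "n_edges_p05": nets[config.alpha].n_edges,
        }
        node_set = list(dict.fromkeys(key_cands + enzyme_ids)) if key_cands else enzyme_ids
        if expr.n_samples >= 3 * config.group_size:
            _nets, summary_df = group_network_comparison(
                expr, blup_res.blup, node_set, group_size=config.group_size, p_max=config.alpha,
            )
            summary_df.to_csv(outdir / "group_networks.tsv", sep="\t", index=False)
            report["network"]["group_summary"] = summary_df.to_dict("records")
    _manifest(outdir, "network", config, inputs, {k: v for k, v in report["network"].items() if k != "group_summary"})
    log.info(
        "funnel narrowing: %d -> %d (wgcna in) -> %d hubs -> %d candidates III -> %d key",
        report["funnel"]["n_candidates_1"],
        report["wgcna"].get("n_filtered_genes", 0),
        len(hubs),
        len(candidates3),
        len(report["network"].get("key_candidates", [])),
    )
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
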