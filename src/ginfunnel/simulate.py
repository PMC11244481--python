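"""Synthetic genotype/trait/expression/annotation generator with a truth ledger.

The generator emulates the data structure of a ~344-cultivar core-collection
study of a root metabolite content trait (mg/g scale, replicated
measurements, CV near 50%): biallelic SNPs in LD blocks with mild
population structure, planted trait QTNs with additive and dominance
effects, an expression matrix with planted trait-correlated co-expression
modules, a 15-gene "key enzyme" panel co-regulated with the trait, and gene
models carrying one ORF of known frame so mutation consequences are
analytically known.

LD is induced by a Gaussian copula (compound-symmetric latent correlation
within a block) rather than a coalescent simulation: it is desk-scale,
gives directly controllable r-squared, and needs no external simulator.
All randomness flows through a single ``numpy.random.default_rng`` (PCG64)
stream per call, so outputs are bit-reproducible for a fixed seed across
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix, GeneModel, GenotypeMatrix, SnpRecord, TraitTable

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class SimConfig:
    """Parameters of the synthetic core-collection dataset.

    Defaults mirror the study conditions being emulated at desk scale:
    344 samples, 4000 SNPs over 24 chromosomes, 600 genes, a 15-gene key
    enzyme panel, 3 trait replicates, trait mean 0.632 mg/g with CV 0.5,
    and a strongest planted module with trait correlation 0.85.
    """

    n_samples: int = 344
    n_snps: int = 4000
    n_chrom: int = 24
    snp_spacing_bp: int = 5000
    ld_block_size: int = 10
    ld_rho: float = 0.9
    n_subpops: int = 2
    fst: float = 0.05
    missing_rate: float = 0.0
    # (snp_index, additive beta in mg/g per alt allele, dominance d in mg/g);
    # None -> two QTNs auto-placed on different chromosomes at PVE ~0.15 each
    planted_qtns: Optional[list[tuple[int, float, float]]] = None
    qtn_pve: float = 0.15
    n_genes: int = 600
    gene_spacing_bp: int = 10000
    gene_length_bp: int = 2000
    # (module size, target module-factor/trait correlation)
    planted_modules: list[tuple[int, float]] = field(
        default_factory=lambda: [(10, 0.85), (15, 0.5), (20, -0.4)]
    )
    # planted-module genes are tightly co-regulated (transcripts of one
    # pathway): pairwise r ~ loading^2, which must survive a soft-threshold
    # power of ~8-12 for hub edges with weight > 0.4 to exist
    within_module_loading: float = 0.95
    expression_link_scale: float = 0.3
    key_enzyme_panel_size: int = 15
    n_zero_inflated: int = 0
    zero_inflated_fraction: float = 0.8
    replicate_count: int = 3
    trait_mean: float = 0.632
    trait_cv: float = 0.5
    # share of non-genetic trait variance that is a persistent sample effect
    sample_effect_share: float = 0.6
    rep_effect_share: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_snps", "n_chrom", "ld_block_size", "n_subpops",
                     "n_genes", "replicate_count", "key_enzyme_panel_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must be in [0, 1)")
        for size, r in self.planted_modules:
            if abs(r) >= 1:
                raise ValueError("module trait correlations must satisfy |r| < 1")
            if size < 1:
                raise ValueError("module sizes must be >= 1")
        if sum(s for s, _ in self.planted_modules) > self.n_genes:
            raise ValueError("module sizes must sum to <= n_genes")
        if self.planted_qtns is not None:
            for idx, beta, d in self.planted_qtns:
                if not (0 <= idx < self.n_snps):
                    raise ValueError(f"planted QTN index {idx} outside SNP panel")
                if not (np.isfinite(beta) and np.isfinite(d)):
                    raise ValueError("QTN effects must be finite")


@dataclass
class SyntheticTruth:
    """Ground-truth ledger sufficient to score every downstream stage."""

    qtn_snp_ids: list[str] = field(default_factory=list)
    qtn_indices: list[int] = field(default_factory=list)
    qtn_betas: list[float] = field(default_factory=list)
    qtn_dominance: list[float] = field(default_factory=list)
    genetic_value: Optional[np.ndarray] = None  # per-sample g
    module_assignment: dict[str, int] = field(default_factory=dict)  # gene -> module idx (-1 background)
    module_trait_r: list[float] = field(default_factory=list)
    key_enzyme_genes: list[str] = field(default_factory=list)
    subpop: Optional[np.ndarray] = None

    def to_json_dict(self) -> dict:
        d = {
            "qtn_snp_ids": self.qtn_snp_ids,
            "qtn_indices": [int(i) for i in self.qtn_indices],
            "qtn_betas": [float(b) for b in self.qtn_betas],
            "qtn_dominance": [float(x) for x in self.qtn_dominance],
            "genetic_value": None if self.genetic_value is None else [float(v) for v in self.genetic_value],
            "module_assignment": {k: int(v) for k, v in self.module_assignment.items()},
            "module_trait_r": [float(r) for r in self.module_trait_r],
            "key_enzyme_genes": self.key_enzyme_genes,
            "subpop": None if self.subpop is None else [int(s) for s in self.subpop],
        }
        return d


# ---------------------------------------------------------------------------
# Genotypes


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Hardy-Weinberg dosages with copula LD blocks and subpopulation structure.

    Each of the two allele copies of a sample is a thresholded Gaussian:
    within an LD block the latent variables share a compound-symmetric
    correlation ``ld_rho``; allele frequencies are drawn uniform(0.05, 0.5)
    and diverge between subpopulations by a Balding-Nichols Beta draw with
    divergence parameter ``fst``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_snps
    # one ancestral frequency per LD block, shared by its SNPs: with
    # per-SNP frequencies the attainable r^2 between block mates would be
    # capped by the frequency mismatch regardless of the copula correlation
    n_blocks = int(np.ceil(m / config.ld_block_size))
    block_p = rng.uniform(0.05, 0.5, size=n_blocks)
    p_anc = np.repeat(block_p, config.ld_block_size)[:m]

    subpop = np.arange(n) % config.n_subpops
    if config.n_subpops > 1 and config.fst > 0:
        a = p_anc * (1 - config.fst) / config.fst
        b = (1 - p_anc) * (1 - config.fst) / config.fst
        p_sub = rng.beta(a[None, :].repeat(config.n_subpops, 0), b[None, :].repeat(config.n_subpops, 0))
        p_sub = np.clip(p_sub, 0.01, 0.99)
    else:
        p_sub = p_anc[None, :].repeat(config.n_subpops, 0)

    # latent gaussians: two gametes per sample, block-correlated across SNPs
    calls = np.empty((n, m), dtype=np.int8)
    rho = config.ld_rho
    for start in range(0, m, config.ld_block_size):
        width = min(config.ld_block_size, m - start)
        z = []
        for _gamete in range(2):
            shared = rng.standard_normal((n, 1))
            indiv = rng.standard_normal((n, width))
            z.append(np.sqrt(rho) * shared + np.sqrt(1 - rho) * indiv)
        thresh = stats.norm.ppf(p_sub[subpop, start : start + width])
        block = (z[0] < thresh).astype(np.int8) + (z[1] < thresh).astype(np.int8)
        calls[:, start : start + width] = block

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        calls[mask] = -1

    snps_per_chrom = int(np.ceil(m / config.n_chrom))
    jitter = rng.integers(0, config.snp_spacing_bp, size=m)
    snps = []
    for j in range(m):
        c = j // snps_per_chrom + 1
        within = j % snps_per_chrom
        # jitter keeps positions strictly increasing within a chromosome
        # while letting SNPs fall inside gene spans
        pos = within * config.snp_spacing_bp + 1 + int(jitter[j])
        snps.append(SnpRecord(id=f"snp{j:05d}", chrom=f"chr{c}", pos=pos, ref="A", alt="G"))
    samples = [f"S{i + 1:03d}" for i in range(n)]
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


# ---------------------------------------------------------------------------
# Trait


def _resolve_qtns(gm: GenotypeMatrix, config: SimConfig, var_total: float,
                  rng: np.random.Generator) -> list[tuple[int, float, float]]:
    if config.planted_qtns is not None:
        return list(config.planted_qtns)
    # auto: two QTNs on different chromosomes, additive beta sized for qtn_pve
    maf = gm.maf()
    chroms = np.array([s.chrom for s in gm.snps])
    uniq = list(dict.fromkeys(chroms))
    picks: list[int] = []
    for chrom in uniq:
        if len(picks) == 2:
            break
        cand = np.where((chroms == chrom) & (maf > 0.2) & (maf < 0.45))[0]
        if cand.size:
            picks.append(int(cand[cand.size // 2]))
    qtns = []
    for idx in picks:
        qtns.append((idx, beta_for_pve(config.qtn_pve, maf[idx], var_total), 0.0))
    return qtns


def beta_for_pve(pve: float, maf: float, var_total: float) -> float:
    """Additive effect giving PVE = 2p(1-p) beta^2 / var_total at HWE."""
    return float(np.sqrt(pve * var_total / (2 * maf * (1 - maf))))


def simulate_trait(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[TraitTable, SyntheticTruth]:
    """Replicated trait records: trait = mu + g + u_sample + w_rep + e, clipped at 0.

    g = sum over planted QTNs of beta * dosage + d * het_indicator; the
    non-genetic variance (total (cv * mean)^2 minus the realized genetic
    variance) is split between a persistent sample effect, a replicate
    (block) effect shared across samples, and residual noise.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = genotypes.n_samples
    var_total = (config.trait_cv * config.trait_mean) ** 2
    qtns = _resolve_qtns(genotypes, config, var_total, rng)

    x = genotypes.dosage(impute=True)
    g = np.zeros(n)
    for idx, beta, d in qtns:
        g += beta * x[:, idx] + d * (genotypes.calls[:, idx] == 1)
    g = g - g.mean()

    var_g = float(np.var(g))
    if var_g > var_total:
        raise ValueError(
            f"planted genetic variance {var_g:.4g} exceeds total trait variance "
            f"{var_total:.4g} (implied heritability > 1)"
        )
    var_env = var_total - var_g
    var_sample = var_env * config.sample_effect_share
    var_rep = var_env * config.rep_effect_share
    var_e = max(var_env - var_sample - var_rep, 0.0)

    u = rng.normal(0.0, np.sqrt(var_sample), size=n)
    w = rng.normal(0.0, np.sqrt(var_rep), size=config.replicate_count)
    rows = []
    for r in range(config.replicate_count):
        e = rng.normal(0.0, np.sqrt(var_e), size=n)
        y = np.clip(config.trait_mean + g + u + w[r] + e, 0.0, None)
        for i, s in enumerate(genotypes.samples):
            rows.append((s, f"rep{r + 1}", y[i]))
    table = TraitTable(records=pd.DataFrame(rows, columns=["sample", "rep", "value"]))
    truth = SyntheticTruth(
        qtn_snp_ids=[genotypes.snps[i].id for i, _, _ in qtns],
        qtn_indices=[i for i, _, _ in qtns],
        qtn_betas=[b for _, b, _ in qtns],
        qtn_dominance=[d for _, _, d in qtns],
        genetic_value=g,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    trait: np.ndarray | pd.Series,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    gene_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
    module_gene_indices: list[list[int]] | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Expression matrix with planted trait-correlated co-expression modules.

    Each planted module is driven by a latent factor correlated with the
    standardized trait at its target r; member genes load on the factor at
    ``within_module_loading`` plus independent noise.  Background genes are
    pure noise.  The key-enzyme panel (ids ``enzyme01`` ...) is drawn from
    the strongest module's factor.  Non-negativity comes from an exponential
    link with a small scale, which preserves Pearson correlations to good
    approximation.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    t = np.asarray(trait, dtype=float)
    n = t.size
    t_std = (t - t.mean()) / t.std() if t.std() > 0 else np.zeros(n)

    if gene_ids is None:
        gene_ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    if len(gene_ids) != config.n_genes:
        raise ValueError("gene_ids length must equal n_genes")

    if module_gene_indices is None:
        module_gene_indices = []
        cursor = 0
        for size, _r in config.planted_modules:
            module_gene_indices.append(list(range(cursor, cursor + size)))
            cursor += size
    if len(module_gene_indices) != len(config.planted_modules):
        raise ValueError("module_gene_indices must match planted_modules")

    latent = np.empty((config.n_genes, n))
    assignment = {g: -1 for g in gene_ids}
    factors = []
    lam = config.within_module_loading
    for mi, ((size, r), idxs) in enumerate(zip(config.planted_modules, module_gene_indices)):
        if len(idxs) != size:
            raise ValueError("module index list size mismatch")
        f = r * t_std + np.sqrt(1 - r**2) * rng.standard_normal(n)
        factors.append(f)
        for gi in idxs:
            latent[gi] = lam * f + np.sqrt(1 - lam**2) * rng.standard_normal(n)
            assignment[gene_ids[gi]] = mi
    module_members = {gi for idxs in module_gene_indices for gi in idxs}
    for gi in range(config.n_genes):
        if gi not in module_members:
            latent[gi] = rng.standard_normal(n)

    # key enzyme panel rides the strongest-|r| module's factor
    strongest = int(np.argmax([abs(r) for _s, r in config.planted_modules])) if config.planted_modules else -1
    panel_ids = [f"enzyme{k + 1:02d}" for k in range(config.key_enzyme_panel_size)]
    panel = np.empty((len(panel_ids), n))
    for k in range(len(panel_ids)):
        if strongest >= 0:
            panel[k] = lam * factors[strongest] + np.sqrt(1 - lam**2) * rng.standard_normal(n)
        else:
            panel[k] = rng.standard_normal(n)

    all_ids = gene_ids + panel_ids
    all_latent = np.vstack([latent, panel])
    base = rng.normal(1.0, 0.25, size=len(all_ids))
    values = np.exp(base[:, None] + config.expression_link_scale * all_latent)

    # optional zero-inflated genes (fixtures for the 70%-zero filter)
    for k in range(config.n_zero_inflated):
        gi = config.n_genes - 1 - k
        zero_idx = rng.choice(n, size=int(np.ceil(config.zero_inflated_fraction * n)), replace=False)
        values[gi, zero_idx] = 0.0

    expr = ExpressionMatrix(genes=all_ids, samples=list(sample_ids), values=values)
    truth = SyntheticTruth(
        module_assignment=assignment,
        module_trait_r=[r for _s, r in config.planted_modules],
        key_enzyme_genes=panel_ids,
    )
    return expr, truth


# ---------------------------------------------------------------------------
# Gene models / sequences


def _random_codons(rng: np.random.Generator, n_codons: int) -> str:
    bases = "ACGT"
    out = []
    while len(out) < n_codons:
        codon = "".join(rng.choice(list(bases), size=3))
        if codon not in STOP_CODONS and codon != "ATG":
            out.append(codon)
    return "".join(out)


def _random_utr(rng: np.random.Generator, length: int) -> str:
    """Sequence free of ATG so the planted ORF start is unambiguous."""
    bases = np.array(list("ACGT"))
    seq = "".join(rng.choice(bases, size=length))
    while "ATG" in seq:
        seq = seq.replace("ATG", "ACG", 1)
    return seq


def make_mrna_with_orf(rng: np.random.Generator, total_len: int, utr5: int, orf_codons: int) -> tuple[str, int, int]:
    """mRNA with exactly one ATG-initiated ORF; returns (seq, orf_start, orf_end) 1-based."""
    orf_len = 3 * orf_codons + 6  # ATG + codons + stop
    utr3 = total_len - utr5 - orf_len
    if utr3 < 0:
        raise ValueError("total_len too short for requested ORF")
    seq = _random_utr(rng, utr5) + "ATG" + _random_codons(rng, orf_codons) + "TAA" + _random_utr(rng, utr3)
    return seq, utr5 + 1, utr5 + orf_len


def simulate_gene_models(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[GeneModel], dict[str, str]]:
    """Tile intron-less genes along the chromosomes and give each an mRNA
    with one ORF of known frame.

    For any SNP of the genotype panel that falls inside a gene span, the
    mRNA base at the mapped position is overwritten with the SNP's REF
    allele, so genomic variants translate consistently onto the transcript.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    chroms = list(dict.fromkeys(s.chrom for s in genotypes.snps))
    genes_per_chrom = int(np.ceil(config.n_genes / len(chroms)))
    genes: list[GeneModel] = []
    fasta: dict[str, str] = {}
    gi = 0
    orf_codons = max((config.gene_length_bp - 220) // 3, 30)
    for chrom in chroms:
        for k in range(genes_per_chrom):
            if gi >= config.n_genes:
                break
            start = k * config.gene_spacing_bp + 1
            end = start + config.gene_length_bp - 1
            gid = f"g{gi + 1:04d}"
            seq, _os, _oe = make_mrna_with_orf(rng, config.gene_length_bp, utr5=100, orf_codons=orf_codons)
            genes.append(GeneModel(id=gid, chrom=chrom, start=start, end=end, strand="+"))
            fasta[gid] = seq
            gi += 1

    # make mRNA sequence consistent with genomic REF alleles
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for s in genotypes.snps:
        for g in by_chrom.get(s.chrom, []):
            if g.start <= s.pos <= g.end and len(s.ref) == 1:
                offset = s.pos - g.start
                seq = fasta[g.id]
                fasta[g.id] = seq[:offset] + s.ref + seq[offset + 1 :]
    for g in genes:
        g.mrna = fasta[g.id]
    return genes, fasta


# ---------------------------------------------------------------------------
# Whole-dataset coordinator


@dataclass
class SyntheticDataset:
    genotypes: GenotypeMatrix
    traits: TraitTable
    expression: ExpressionMatrix
    gene_models: list[GeneModel]
    fasta: dict[str, str]
    truth: SyntheticTruth


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate a coherent dataset: the strongest planted module's genes (and
    hence the key-enzyme co-regulation) are placed inside the first planted
    QTN's ±500 kb window so the full funnel has a recoverable ground truth."""
    rng = np.random.default_rng(config.seed)
    gm = simulate_genotypes(config, rng)
    traits, truth_t = simulate_trait(gm, config, rng)
    genes, fasta = simulate_gene_models(gm, config, rng)

    # place the strongest module's genes near the first QTN
    module_gene_indices: list[list[int]] | None = None
    if truth_t.qtn_indices and config.planted_modules:
        qtn_snp = gm.snps[truth_t.qtn_indices[0]]
        near = [
            i
            for i, g in enumerate(genes)
            if g.chrom == qtn_snp.chrom and g.start <= qtn_snp.pos + 500_000 and g.end >= qtn_snp.pos - 500_000
        ]
        # closest genes first, so module (and hence hub) genes overlap the
        # QTN's LD neighbourhood and carry trait-associated SNPs
        near.sort(key=lambda i: abs((genes[i].start + genes[i].end) // 2 - qtn_snp.pos))
        strongest = int(np.argmax([abs(r) for _s, r in config.planted_modules]))
        sizes = [s for s, _r in config.planted_modules]
        if len(near) >= sizes[strongest]:
            module_gene_indices = []
            used = set()
            for mi, size in enumerate(sizes):
                if mi == strongest:
                    idxs = near[:size]
                else:
                    pool = [i for i in range(len(genes)) if i not in used and i not in set(near[: sizes[strongest]])]
                    idxs = pool[:size]
                module_gene_indices.append(idxs)
                used.update(idxs)

    blup_like = traits.sample_means().reindex(gm.samples).to_numpy()
    expr, truth_e = simulate_expression(
        blup_like,
        config,
        rng,
        gene_ids=[g.id for g in genes],
        sample_ids=list(gm.samples),
        module_gene_indices=module_gene_indices,
    )
    truth = SyntheticTruth(
        qtn_snp_ids=truth_t.qtn_snp_ids,
        qtn_indices=truth_t.qtn_indices,
        qtn_betas=truth_t.qtn_betas,
        qtn_dominance=truth_t.qtn_dominance,
        genetic_value=truth_t.genetic_value,
        module_assignment=truth_e.module_assignment,
        module_trait_r=truth_e.module_trait_r,
        key_enzyme_genes=truth_e.key_enzyme_genes,
        subpop=np.arange(config.n_samples) % config.n_subpops,
    )
    return SyntheticDataset(gm, traits, expr, genes, fasta, truth)
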