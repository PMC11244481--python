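"""Single-locus genome-wide association: kinship, structure PCs, LD pruning,
the six fixed/mixed model scans, and Bonferroni thresholding.

The six model tags follow the usual naming: GLM (naive regression), GLM_Q
and GLM_PCA (structure covariates), MLM_K (polygenic random effect with
kinship covariance), MLM_QK and MLM_PCAK (both).  STRUCTURE-style Q
matrices are represented by principal-component scores throughout; GLM_Q
and GLM_PCA differ only in how many components are used.

The mixed model uses the spectral decomposition of the kinship matrix with
variance components estimated once on the null model (the
population-parameters-previously-determined shortcut) and a per-marker
generalized-least-squares F test.  Using the F reference for both GLM and
MLM makes the two scans exactly equal in the limit of zero polygenic
variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_io import GenotypeMatrix

log = logging.getLogger(__name__)

SINGLE_LOCUS_TAGS = ("GLM", "GLM_Q", "GLM_PCA", "MLM_K", "MLM_QK", "MLM_PCAK")


@dataclass
class KinshipMatrix:
    samples: list[str]
    values: np.ndarray  # n x n, symmetric PSD (stabilized)


@dataclass
class StructureCovariates:
    samples: list[str]
    scores: np.ndarray  # n x q, mean-zero columns


@dataclass
class AssocResult:
    snp: str
    chrom: str
    pos: int
    model: str
    beta: float
    p: float
    pve: float
    flagged: bool = False


def results_to_frame(results: list[AssocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.snp, r.chrom, r.pos, r.model, r.beta, r.p, r.pve, r.flagged) for r in results],
        columns=["snp", "chrom", "pos", "model", "beta", "p", "pve", "flagged"],
    )


# ---------------------------------------------------------------------------
# Kinship and structure


def compute_kinship(genotypes: GenotypeMatrix, stabilize: float = 1e-6) -> KinshipMatrix:
    """Centered-genotype cross-product kinship K = W W' / c.

    W = dosage - 2*phat per SNP (missing calls mean-imputed) and
    c = 2 * sum phat (1 - phat); a small ridge is added to the diagonal so
    downstream decompositions are numerically positive semidefinite.
    """
    if genotypes.n_samples < 2 or genotypes.n_snps < 2:
        raise ValueError("need >= 2 samples and >= 2 SNPs for kinship")
    x = genotypes.dosage(impute=True)
    p = x.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("kinship undefined: all SNPs monomorphic")
    w = x[:, poly] - 2 * p[poly]
    c = 2 * np.sum(p[poly] * (1 - p[poly]))
    k = w @ w.T / c
    k[np.diag_indices_from(k)] += stabilize
    return KinshipMatrix(samples=list(genotypes.samples), values=k)


def compute_pcs(genotypes: GenotypeMatrix, q: int) -> StructureCovariates:
    """Top-q principal-component scores of the centered genotype matrix.

    Sign convention: within each component the loading of largest magnitude
    is made positive, so results are deterministic across LAPACK builds.
    """
    n = genotypes.n_samples
    if q >= n:
        raise ValueError("q must be < n_samples")
    if q == 0:
        return StructureCovariates(samples=list(genotypes.samples), scores=np.zeros((n, 0)))
    x = genotypes.dosage(impute=True)
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    scores = u[:, :q] * s[:q]
    for j in range(scores.shape[1]):
        v = vt[j]
        if v[np.argmax(np.abs(v))] < 0:
            scores[:, j] = -scores[:, j]
    scores = scores - scores.mean(axis=0)
    return StructureCovariates(samples=list(genotypes.samples), scores=scores)


# ---------------------------------------------------------------------------
# LD pruning


def _pairwise_r2(x: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns (mean-imputed input)."""
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    sd[sd == 0] = np.inf  # monomorphic: correlation treated as 0
    r = (xc / sd).T @ (xc / sd) / x.shape[0]
    return r**2


def ld_prune(
    genotypes: GenotypeMatrix,
    window: int = 50,
    step: int = 50,
    r2_max: float = 0.2,
) -> list[str]:
    """Greedy windowed LD pruning; returns retained SNP ids.

    Within each window of ``window`` SNPs, while any retained pair has
    dosage r^2 >= r2_max, the member with the lower MAF is dropped (tie:
    the later position goes); the window then slides by ``step`` SNPs.
    """
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    x = genotypes.dosage(impute=True)
    maf = genotypes.maf()
    m = genotypes.n_snps
    keep = np.ones(m, dtype=bool)
    for start in range(0, m, step):
        idx = np.array([j for j in range(start, min(start + window, m)) if keep[j]])
        if idx.size < 2:
            continue
        r2 = _pairwise_r2(x[:, idx])
        np.fill_diagonal(r2, 0.0)
        active = np.ones(idx.size, dtype=bool)
        while True:
            sub = np.where(active)[0]
            if sub.size < 2:
                break
            block = r2[np.ix_(sub, sub)]
            i, j = np.unravel_index(np.argmax(block), block.shape)
            if block[i, j] < r2_max:
                break
            a, b = idx[sub[i]], idx[sub[j]]
            # drop the lower-MAF member; tie -> later position
            if maf[a] < maf[b] or (maf[a] == maf[b] and a > b):
                drop = sub[i]
            else:
                drop = sub[j]
            active[drop] = False
            keep[idx[drop]] = False
        if start + window >= m:
            break
    return [genotypes.snps[j].id for j in range(m) if keep[j]]


# ---------------------------------------------------------------------------
# GLM scan


def _f_pvalue(fstat: float, df2: int) -> float:
    if df2 <= 0 or not np.isfinite(fstat):
        return 1.0
    return float(stats.f.sf(fstat, 1, df2))


def glm_scan(
    genotypes: GenotypeMatrix,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    model_tag: str = "GLM",
) -> list[AssocResult]:
    """Per-SNP ordinary least squares of the trait on dosage plus covariates.

    p is the marker's 1-df partial F test; PVE is the partial R^2
    (reduction in residual sum of squares relative to the covariate-only
    model).  Missing calls are handled complete-case per SNP; monomorphic
    SNPs return beta=0, p=1, flagged.
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    C = np.ones((n, 1)) if covariates is None or covariates.size == 0 else np.column_stack([np.ones(n), covariates])
    x = genotypes.dosage(impute=False)
    results: list[AssocResult] = []
    for j, snp in enumerate(genotypes.snps):
        xj = x[:, j]
        mask = ~np.isnan(xj)
        xs, ys, Cs = xj[mask], y[mask], C[mask]
        res = _ols_marker(xs, ys, Cs)
        results.append(AssocResult(snp=snp.id, chrom=snp.chrom, pos=snp.pos, model=model_tag, **res))
    return results


def _ols_marker(xs: np.ndarray, ys: np.ndarray, Cs: np.ndarray) -> dict:
    ns = ys.size
    k = Cs.shape[1]
    if ns <= k + 1 or np.allclose(xs, xs[0] if ns else 0):
        return dict(beta=0.0, p=1.0, pve=0.0, flagged=True)
    beta0, rss0 = _lstsq_rss(Cs, ys)
    X1 = np.column_stack([Cs, xs])
    beta1, rss1 = _lstsq_rss(X1, ys)
    df2 = ns - X1.shape[1]
    if rss1 <= 0:
        return dict(beta=float(beta1[-1]), p=0.0, pve=1.0, flagged=False)
    f = (rss0 - rss1) / (rss1 / df2)
    pve = max((rss0 - rss1) / rss0, 0.0) if rss0 > 0 else 0.0
    return dict(beta=float(beta1[-1]), p=_f_pvalue(f, df2), pve=float(pve), flagged=False)


def _lstsq_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _res, _rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return beta, float(r @ r)


# ---------------------------------------------------------------------------
# MLM scan (EMMA-style spectral REML + P3D GLS)


def _reml_loglik(log_delta: float, d: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> float:
    """Restricted log-likelihood of the rotated null model as a function of
    delta = sigma_e^2 / sigma_g^2 (up to constants)."""
    delta = np.exp(log_delta)
    w = d + delta
    n, p = Xr.shape
    Wi = 1.0 / w
    XtWX = Xr.T @ (Xr * Wi[:, None])
    XtWy = Xr.T @ (yr * Wi)
    beta = np.linalg.solve(XtWX, XtWy)
    r = yr - Xr @ beta
    rss = float(r @ (r * Wi))
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    ll = -0.5 * (
        (n - p) * np.log(rss / (n - p))
        + np.sum(np.log(w))
        + logdet_xwx
        + (n - p)
    )
    return ll


def null_reml(
    trait: np.ndarray,
    kinship: KinshipMatrix,
    covariates: np.ndarray | None = None,
    grid: tuple[float, float, int] = (-8.0, 8.0, 120),
) -> dict:
    """REML of the null mixed model over the spectral decomposition of K.

    Returns the eigen-rotation and variance components used for the
    per-marker P3D scans.  Grid search over log10(delta) followed by
    bounded refinement; raises on non-finite likelihoods.
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    K = kinship.values
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    C = np.ones((n, 1)) if covariates is None or covariates.size == 0 else np.column_stack([np.ones(n), covariates])
    yr = U.T @ y
    Cr = U.T @ C
    lo, hi, npts = grid
    lds = np.linspace(lo * np.log(10), hi * np.log(10), npts)
    lls = np.array([_reml_loglik(ld, d, yr, Cr) for ld in lds])
    if not np.isfinite(lls).any():
        raise RuntimeError("REML failed: no finite restricted likelihood on the grid")
    best = int(np.nanargmax(lls))
    a = lds[max(best - 1, 0)]
    b = lds[min(best + 1, npts - 1)]
    opt = optimize.minimize_scalar(lambda ld: -_reml_loglik(ld, d, yr, Cr), bounds=(a, b), method="bounded")
    log_delta = float(opt.x) if np.isfinite(opt.x) else float(lds[best])
    delta = float(np.exp(log_delta))
    # sigma_g^2 from profiled REML residual
    w = d + delta
    Wi = 1.0 / w
    XtWX = Cr.T @ (Cr * Wi[:, None])
    beta = np.linalg.solve(XtWX, Cr.T @ (yr * Wi))
    r = yr - Cr @ beta
    sigma_g2 = float(r @ (r * Wi)) / (n - C.shape[1])
    return {
        "delta": delta,
        "sigma_g2": sigma_g2,
        "sigma_e2": sigma_g2 * delta,
        "eigvals": d,
        "rotation": U,
        "loglik": float(-opt.fun),
    }


def mlm_scan(
    genotypes: GenotypeMatrix,
    trait: np.ndarray,
    kinship: KinshipMatrix,
    covariates: np.ndarray | None = None,
    model_tag: str = "MLM_K",
    null_fit: dict | None = None,
) -> list[AssocResult]:
    """Mixed-model scan: y = Xb + x_s b_s + u + e, u ~ N(0, sigma_g^2 K).

    Variance components come from the null model only (P3D); each marker is
    then tested by GLS on the rotated data with a 1-df F test, so that at
    delta -> inf (no polygenic variance) the scan reduces exactly to the GLM.
    Missing dosages are mean-imputed here (the rotation mixes samples, so
    complete-case per SNP is not available in the rotated space).
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    if null_fit is None:
        null_fit = null_reml(trait, kinship, covariates)
    U = null_fit["rotation"]
    d = null_fit["eigvals"]
    delta = null_fit["delta"]
    w = np.sqrt(1.0 / (d + delta))
    C = np.ones((n, 1)) if covariates is None or covariates.size == 0 else np.column_stack([np.ones(n), covariates])
    yt = (U.T @ y) * w
    Ct = (U.T @ C) * w[:, None]
    x = genotypes.dosage(impute=True)
    xt = (U.T @ x) * w[:, None]
    results: list[AssocResult] = []
    mono = genotypes.maf() == 0
    for j, snp in enumerate(genotypes.snps):
        if mono[j]:
            results.append(AssocResult(snp=snp.id, chrom=snp.chrom, pos=snp.pos, model=model_tag,
                                       beta=0.0, p=1.0, pve=0.0, flagged=True))
            continue
        res = _ols_marker(xt[:, j], yt, Ct)
        results.append(AssocResult(snp=snp.id, chrom=snp.chrom, pos=snp.pos, model=model_tag, **res))
    return results


def run_six_models(
    genotypes: GenotypeMatrix,
    trait: np.ndarray,
    q_structure: int = 3,
    q_pca: int = 3,
) -> dict[str, list[AssocResult]]:
    """Run all six single-locus models and return results keyed by tag."""
    kin = compute_kinship(genotypes)
    pcs_q = compute_pcs(genotypes, q_structure).scores
    pcs_p = compute_pcs(genotypes, q_pca).scores
    out: dict[str, list[AssocResult]] = {}
    out["GLM"] = glm_scan(genotypes, trait, None, "GLM")
    out["GLM_Q"] = glm_scan(genotypes, trait, pcs_q, "GLM_Q")
    out["GLM_PCA"] = glm_scan(genotypes, trait, pcs_p, "GLM_PCA")
    out["MLM_K"] = mlm_scan(genotypes, trait, kin, None, "MLM_K")
    out["MLM_QK"] = mlm_scan(genotypes, trait, kin, pcs_q, "MLM_QK")
    out["MLM_PCAK"] = mlm_scan(genotypes, trait, kin, pcs_p, "MLM_PCAK")
    return out


# ---------------------------------------------------------------------------
# Thresholds / diagnostics / plots


def bonferroni_threshold(n_tests: int, fwer: float = 0.01) -> tuple[float, float]:
    """Family-wise threshold fwer / n_tests and its -log10."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < fwer < 1:
        raise ValueError("fwer must be in (0, 1)")
    p = fwer / n_tests
    return p, float(-np.log10(p))


def genomic_inflation(pvalues: np.ndarray) -> float:
    """Genomic-control lambda: median observed chi^2(1) over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p) & (p > 0) & (p <= 1)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


def manhattan_qq_plot(
    results: list[AssocResult],
    threshold: float,
    path_prefix: str,
) -> tuple[str, str]:
    """Write a Manhattan plot and a QQ plot; returns the two file paths."""
    if not results:
        raise ValueError("no association results to plot")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = results_to_frame(results)
    df["logp"] = -np.log10(np.clip(df["p"], 1e-300, 1.0))
    chroms = list(dict.fromkeys(df["chrom"]))
    fig, ax = plt.subplots(figsize=(10, 3.2))
    offset = 0
    ticks = []
    for ci, chrom in enumerate(chroms):
        sub = df[df["chrom"] == chrom]
        ax.scatter(offset + sub["pos"], sub["logp"], s=4, color=["#33658a", "#f26419"][ci % 2])
        ticks.append(offset + sub["pos"].median())
        offset += sub["pos"].max() + 1
    ax.axhline(-np.log10(threshold), color="red", linestyle="--", linewidth=1)
    ax.set_xticks(ticks)
    ax.set_xticklabels(chroms, rotation=90, fontsize=6)
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(df["model"].iloc[0])
    man_path = f"{path_prefix}_manhattan.png"
    fig.tight_layout()
    fig.savefig(man_path, dpi=120)
    plt.close(fig)

    obs = np.sort(df["logp"].to_numpy())[::-1]
    exp = -np.log10((np.arange(1, obs.size + 1) - 0.5) / obs.size)
    fig, ax = plt.subplots(figsize=(3.4, 3.4))
    ax.scatter(exp, obs, s=5, color="#33658a")
    lim = max(exp.max(), obs.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", linewidth=1)
    ax.set_xlabel("expected " + r"$-\log_{10} p$")
    ax.set_ylabel("observed " + r"$-\log_{10} p$")
    qq_path = f"{path_prefix}_qq.png"
    fig.tight_layout()
    fig.savefig(qq_path, dpi=120)
    plt.close(fig)
    return man_path, qq_path
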