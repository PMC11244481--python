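"""Weighted co-expression analysis: filtering, outlier removal, soft
threshold, topological overlap, module detection, module-trait correlation
and hub-gene selection.

The network is unsigned (adjacency |cor|^beta).  Module detection uses
average-linkage clustering on 1 - TOM with a static tree cut: branches
below a fixed cut height become modules, branches smaller than the minimum
size fall into the unassigned "grey" set.  A static cut is deterministic
and transparent at desk scale, which is why it is used here instead of a
dynamic branch-cutting heuristic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform

from .data_io import ExpressionMatrix

log = logging.getLogger(__name__)

# color labels in size-rank order, as co-expression tools conventionally do
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
]
GREY = "grey"


@dataclass
class CoexprModule:
    color: str
    genes: list[str]
    eigengene: np.ndarray | None = None
    trait_r: float | None = None
    trait_p: float | None = None


@dataclass
class SoftThresholdReport:
    powers: np.ndarray
    fit_r2: np.ndarray  # signed scale-free fit, clipped at 0
    mean_connectivity: np.ndarray
    chosen_power: float


# ---------------------------------------------------------------------------
# Filtering / outliers


def filter_expression(expr: ExpressionMatrix, zero_fraction: float = 0.70) -> ExpressionMatrix:
    """Drop genes whose expression is zero in strictly more than
    ``zero_fraction`` of the samples (a gene at exactly the threshold is
    retained)."""
    frac_zero = (expr.values == 0).mean(axis=1)
    keep = frac_zero <= zero_fraction
    if not keep.any():
        raise ValueError("zero-fraction filter removed every gene")
    kept = [g for g, k in zip(expr.genes, keep) if k]
    return ExpressionMatrix(kept, list(expr.samples), expr.values[keep])


def remove_outlier_samples(
    expr: ExpressionMatrix,
    mad_factor: float = 3.0,
    force: bool = False,
) -> tuple[ExpressionMatrix, list[str]]:
    """Average-linkage clustering on Euclidean sample distances; samples whose
    leaf merge height exceeds median + mad_factor * MAD are dropped.

    Returns (filtered matrix, dropped sample ids).  If more than 20% of the
    samples are flagged, an explicit ``force=True`` is required — a flag
    rate that high usually means a batch problem, not a few bad samples.
    """
    n = expr.n_samples
    if n <= 2:
        log.warning("too few samples (%d) for outlier detection; no-op", n)
        return expr, []
    profiles = expr.values.T  # samples x genes
    Zl = linkage(profiles, method="average", metric="euclidean")
    # height at which each leaf first merges
    leaf_height = np.full(n, np.nan)
    cluster_members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for k, (a, b, h, _cnt) in enumerate(Zl):
        for node in (int(a), int(b)):
            for leaf in cluster_members[node]:
                if np.isnan(leaf_height[leaf]):
                    leaf_height[leaf] = h
        cluster_members[n + k] = cluster_members[int(a)] + cluster_members[int(b)]
    # a sample is an outlier when it sits above a clear break in the leaf
    # merge heights: even homogeneous data always has a "last" sample, so a
    # plain quantile cutoff would flag somebody on every dataset.  The break
    # must exceed mad_factor * MAD of the tree's merge heights to count.
    heights = Zl[:, 2]
    mad = stats.median_abs_deviation(heights)
    order = np.argsort(leaf_height)
    sorted_h = leaf_height[order]
    gaps = np.diff(sorted_h)
    upper = gaps[len(gaps) // 2 :]  # only breaks in the upper half qualify
    flagged = np.array([], dtype=int)
    if upper.size and upper.max() > mad_factor * (mad if mad > 0 else np.finfo(float).eps):
        gap_at = len(gaps) // 2 + int(np.argmax(upper))
        flagged = order[gap_at + 1 :]
    if flagged.size > 0.2 * n and not force:
        raise ValueError(
            f"{flagged.size}/{n} samples flagged as outliers; pass force=True to drop them anyway"
        )
    dropped = [expr.samples[i] for i in flagged]
    keep = [s for s in expr.samples if s not in set(dropped)]
    return expr.subset_samples(keep), dropped


# ---------------------------------------------------------------------------
# Adjacency / soft threshold / TOM


def adjacency_matrix(expr: ExpressionMatrix, power: float) -> np.ndarray:
    """Unsigned adjacency a_ij = |cor(x_i, x_j)|^power with zero diagonal."""
    r = np.corrcoef(expr.values)
    r = np.nan_to_num(r, nan=0.0)
    a = np.abs(r) ** power
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit of a connectivity vector.

    R^2 of log10 p(k) vs log10 mean-k over connectivity bins, negated when
    the slope is positive (a scale-free network must have a decreasing
    degree distribution); empty bins are skipped.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 3:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.digitize(k, edges[1:-1])
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0
    slope, _inter, r, _p, _se = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r**2)


def pick_soft_threshold(
    expr: ExpressionMatrix,
    powers: np.ndarray | None = None,
    r2_target: float = 0.85,
) -> SoftThresholdReport:
    """Evaluate candidate powers and choose the smallest with signed fit
    >= r2_target, falling back to the argmax when none reaches it.

    The default grid includes half-integer powers 1-20.
    """
    if expr.n_genes < 3:
        raise ValueError("need at least 3 genes to evaluate soft thresholds")
    if powers is None:
        powers = np.arange(1.0, 20.5, 0.5)
    fits = np.empty(powers.size)
    meank = np.empty(powers.size)
    for i, beta in enumerate(powers):
        a = adjacency_matrix(expr, beta)
        k = a.sum(axis=1)
        fits[i] = scale_free_fit(k)
        meank[i] = float(k.mean())
    # selection uses a 3-point median filter of the fit curve: the binned
    # fit statistic is noisy in the power, and an isolated spike must not
    # pick a power at which genuinely distinct modules are still entangled
    if fits.size >= 3:
        smooth = fits.copy()
        smooth[1:-1] = np.median(
            np.column_stack([fits[:-2], fits[1:-1], fits[2:]]), axis=1
        )
    else:
        smooth = fits
    reached = np.where(smooth >= r2_target)[0]
    chosen = powers[reached[0]] if reached.size else powers[int(np.argmax(smooth))]
    return SoftThresholdReport(
        powers=powers, fit_r2=np.clip(fits, 0.0, 1.0),
        mean_connectivity=meank, chosen_power=float(chosen),
    )


def tom_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij),
    with l_ij = sum_u a_iu a_uj (u != i, j) and unit diagonal."""
    a = np.asarray(adjacency, dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # includes u=i and u=j terms, both zero because diag(a)=0
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


# ---------------------------------------------------------------------------
# Modules


def detect_modules(
    tom: np.ndarray,
    gene_ids: list[str],
    min_module_size: int = 5,
    cut_height: float | None = None,
) -> list[CoexprModule]:
    """Average-linkage clustering on 1 - TOM with a static cut.

    ``cut_height`` defaults to 0.99 of the maximum merge height (high
    enough that unclustered background splinters into sub-minimum grey
    fragments, low enough that distinct tight modules merging just below
    the root stay separate); branches below the cut with at least
    ``min_module_size`` members become modules, labelled by size rank;
    everything else is grey.
    """
    n = len(gene_ids)
    if tom.shape != (n, n):
        raise ValueError("TOM shape does not match gene list")
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2, 0.0, None)
    Zl = linkage(squareform(diss, checks=False), method="average")
    if cut_height is None:
        cut_height = 0.99 * float(Zl[:, 2].max()) if len(Zl) else 0.0
    labels = fcluster(Zl, t=cut_height, criterion="distance")
    modules: list[CoexprModule] = []
    grey: list[str] = []
    clusters: dict[int, list[str]] = {}
    for gid, lab in zip(gene_ids, labels):
        clusters.setdefault(int(lab), []).append(gid)
    sized = sorted(
        (genes for genes in clusters.values()),
        key=lambda gs: (-len(gs), gs[0]),
    )
    ci = 0
    for genes in sized:
        if len(genes) >= min_module_size:
            color = MODULE_COLORS[ci % len(MODULE_COLORS)]
            if ci >= len(MODULE_COLORS):
                color = f"{color}{ci // len(MODULE_COLORS) + 1}"
            modules.append(CoexprModule(color=color, genes=genes))
            ci += 1
        else:
            grey.extend(genes)
    if grey:
        modules.append(CoexprModule(color=GREY, genes=sorted(grey)))
    return modules


def module_eigengene(expr: ExpressionMatrix, genes: list[str]) -> np.ndarray:
    """First principal component of the standardized module expression,
    sign-fixed to correlate positively with the module's mean profile."""
    sub = expr.subset_genes(genes)
    x = sub.values
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    xs = (x - x.mean(axis=1, keepdims=True)) / sd
    if xs.shape[0] == 1:
        return xs[0]
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    pc = vt[0] * s[0]
    mean_profile = xs.mean(axis=0)
    if np.corrcoef(pc, mean_profile)[0, 1] < 0:
        pc = -pc
    return pc


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p of a Pearson correlation via the t transform."""
    r = float(np.clip(r, -1.0, 1.0))
    if n < 3:
        return 1.0
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def module_trait(
    modules: list[CoexprModule],
    expr: ExpressionMatrix,
    trait: np.ndarray,
) -> list[CoexprModule]:
    """Annotate each module with its eigengene and eigengene-trait r and p."""
    t = np.asarray(trait, dtype=float)
    for mod in modules:
        if mod.color == GREY:
            continue
        eg = module_eigengene(expr, mod.genes)
        r = float(np.corrcoef(eg, t)[0, 1]) if eg.std() > 0 and t.std() > 0 else 0.0
        mod.eigengene = eg
        mod.trait_r = r
        mod.trait_p = correlation_pvalue(r, t.size)
    return modules


def key_module(modules: list[CoexprModule]) -> CoexprModule:
    """Module with the largest |eigengene-trait correlation|."""
    scored = [m for m in modules if m.trait_r is not None]
    if not scored:
        raise ValueError("no annotated modules; run module_trait first")
    return max(scored, key=lambda m: abs(m.trait_r))


def select_hubs(
    module: CoexprModule,
    adjacency: np.ndarray,
    gene_ids: list[str],
    weight_min: float = 0.4,
    top_k: int = 5,
) -> list[str]:
    """Top-k genes by intramodular connectivity on edges with weight > weight_min.

    Connectivity is the weighted degree of the thresholded within-module
    subgraph; ties break lexicographically by gene id.  Returns every
    member when the module has fewer than top_k genes with surviving edges.
    """
    pos = {g: i for i, g in enumerate(gene_ids)}
    idx = [pos[g] for g in module.genes]
    sub = adjacency[np.ix_(idx, idx)].copy()
    sub[sub <= weight_min] = 0.0
    degree = sub.sum(axis=1)
    if not (degree > 0).any():
        log.info("module %s: no edge exceeds weight %.2f", module.color, weight_min)
        return []
    order = sorted(range(len(idx)), key=lambda i: (-degree[i], module.genes[i]))
    return [module.genes[i] for i in order[:top_k]]
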