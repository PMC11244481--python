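"""Per-sample BLUP of a replicated trait under a two-random-effect model.

Model: y = mu + u_sample + u_rep + e with independent Gaussian random
effects for sample (cultivar) and replicate (trial/block).  Variance
components are estimated by EM-REML on the mixed-model equations; the
de-noised trait reported downstream is mu + BLUP(u_sample), which keeps the
mg/g scale so genotype-group impact rates stay interpretable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import TraitTable

log = logging.getLogger(__name__)


@dataclass
class BlupResult:
    blup: pd.Series  # per-sample mu + predicted sample effect (mg/g)
    var_sample: float
    var_rep: float
    var_error: float
    mu: float
    converged: bool
    n_iter: int

    @property
    def variance_components(self) -> dict[str, float]:
        return {
            "var_sample": self.var_sample,
            "var_rep": self.var_rep,
            "var_error": self.var_error,
        }


def _incidence(labels: pd.Series) -> tuple[np.ndarray, list]:
    levels = list(pd.unique(labels))
    idx = {l: k for k, l in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), [idx[l] for l in labels]] = 1.0
    return Z, levels


def fit_blup(
    traits: TraitTable,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> BlupResult:
    """EM-REML fit of y = mu + u_sample + u_rep + e; returns mu + BLUP(u_sample).

    Variance components are floored at zero.  Non-convergence after
    ``max_iter`` iterations is flagged and the last iterate returned.  A
    single replicate level fixes the replicate variance at zero with a
    warning.
    """
    df = traits.records
    y = df["value"].to_numpy(dtype=float)
    n = y.size
    Z1, samples = _incidence(df["sample"])
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to fit the model")
    Z2, reps = _incidence(df["rep"])
    use_rep = len(reps) > 1
    if not use_rep:
        warnings.warn("single replicate level: replicate variance fixed at 0")

    q1, q2 = Z1.shape[1], Z2.shape[1]
    var_y = float(np.var(y, ddof=1)) if n > 1 else 0.0
    if var_y < 1e-30:
        # degenerate: all measurements identical
        mu = float(y[0]) if n else 0.0
        return BlupResult(
            blup=pd.Series(mu, index=pd.Index(samples, name="sample")),
            var_sample=0.0, var_rep=0.0, var_error=0.0, mu=mu, converged=True, n_iter=0,
        )

    s1 = s2 = se = var_y / 3.0
    if not use_rep:
        s2 = 0.0
    X = np.ones((n, 1))
    p = 1
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lam1 = se / max(s1, 1e-12)
        lam2 = se / max(s2, 1e-12) if use_rep and s2 > 1e-12 else None
        blocks = [X, Z1] + ([Z2] if lam2 is not None else [])
        T = np.hstack(blocks)
        C = T.T @ T
        off = p
        C[off : off + q1, off : off + q1] += lam1 * np.eye(q1)
        if lam2 is not None:
            C[off + q1 :, off + q1 :] += lam2 * np.eye(q2)
        rhs = T.T @ y
        Cinv = np.linalg.pinv(C)
        sol = Cinv @ rhs
        beta = sol[:p]
        u1 = sol[p : p + q1]
        u2 = sol[p + q1 :] if lam2 is not None else np.zeros(q2)

        resid = y - T @ sol
        new_se = float((y @ resid) / (n - p))
        C11 = Cinv[p : p + q1, p : p + q1]
        new_s1 = float((u1 @ u1 + new_se * np.trace(C11)) / q1)
        if lam2 is not None:
            C22 = Cinv[p + q1 :, p + q1 :]
            new_s2 = float((u2 @ u2 + new_se * np.trace(C22)) / q2)
        else:
            new_s2 = 0.0
        new_se = max(new_se, 1e-12)
        new_s1 = max(new_s1, 0.0)
        new_s2 = max(new_s2, 0.0)
        delta = abs(new_s1 - s1) + abs(new_s2 - s2) + abs(new_se - se)
        scale = s1 + s2 + se + 1e-30
        s1, s2, se = new_s1, new_s2, new_se
        if delta / scale < tol:
            converged = True
            break
    if not converged:
        log.warning("EM-REML did not converge in %d iterations (last delta ratio used)", max_iter)

    mu = float(beta[0])
    blup = pd.Series(mu + u1, index=pd.Index(samples, name="sample"))
    return BlupResult(
        blup=blup, var_sample=s1, var_rep=s2 if use_rep else 0.0,
        var_error=se, mu=mu, converged=converged, n_iter=it,
    )


def ks_normality(values: np.ndarray) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against N(xbar, s^2).

    Parameters are estimated from the data and no small-sample (Lilliefors)
    correction is applied, matching common statistics-package defaults; the
    resulting p-value is conservative, which the caller should keep in mind
    when reading borderline results.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError("need n >= 8 for the K-S normality test")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("zero variance: normality test undefined")
    d, p = stats.kstest(x, "norm", args=(x.mean(), s))
    return float(d), float(p)
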