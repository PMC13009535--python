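"""Path (mediation) models: group -> mediator -> brain, bootstrap inference.

The "structural equation model" for this three-variable structure with shared
covariates is saturated, so its maximum-likelihood estimates coincide with
two ordinary least-squares equations::

    mediator = a * group              + covariates + e1
    brain    = c' * group + b * mediator + covariates + e2

The indirect effect is a * b and the total effect obeys the exact linear-path
identity c = c' + a * b. Inference is by nonparametric subject-resampling
bootstrap: per-path p = 2 Phi(-|estimate / bootstrap SE|) with BH-FDR across
the paths of one model, and a bias-corrected (BC) percentile interval for
a * b, deemed significant when the interval excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regional_models import bh_fdr

__all__ = ["PathModel", "brain_composite", "fit_path_model"]

DEFAULT_COVARIATES = ("age", "sex", "rms", "icv")


@dataclass
class PathModel:
    """Estimates, bootstrap SEs, p-values and the BC interval for a*b."""

    a: float
    b: float
    c_prime: float
    c_total: float
    indirect: float
    boot_se: dict[str, float]
    p: dict[str, float]
    p_adj: dict[str, float]
    ci_indirect: tuple[float, float]
    significant_indirect: bool
    n_boot: int
    seed: int


def brain_composite(
    gradients: np.ndarray, factor: np.ndarray, n_regions: int = 15
) -> tuple[np.ndarray, np.ndarray]:
    """Composite brain score from the factor's top regions.

    Per-region Pearson correlation of the subject x parcel gradient values
    with the factor; the ``n_regions`` regions with the largest |r| (ties
    broken by parcel id) are each z-scored across subjects and averaged.
    Note the selection step reuses the factor, so the composite's correlation
    with that factor is optimistically biased — by design, it mirrors the
    published procedure and is not an unbiased effect estimate.

    Returns ``(composite, selected_region_indices)``.
    """
    g = np.asarray(gradients, dtype=float)
    f = np.asarray(factor, dtype=float)
    if g.shape[0] != f.size:
        raise ValueError("gradients and factor must cover the same subjects")
    if g.shape[0] < 16:
        raise ValueError("need at least 16 subjects")
    if np.std(f) == 0:
        raise ValueError("constant factor")
    fz = (f - f.mean()) / f.std()
    gz = g - g.mean(axis=0, keepdims=True)
    sd = g.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (gz.T @ fz) / (len(f) * sd)
    r = np.nan_to_num(r)
    k = min(n_regions, g.shape[1])
    # stable sort on (-|r|, parcel id): ties go to the lower parcel id
    selected = np.lexsort((np.arange(g.shape[1]), -np.abs(r)))[:k]
    selected = np.sort(selected)
    cols = g[:, selected]
    colz = (cols - cols.mean(axis=0)) / cols.std(axis=0, ddof=0)
    return colz.mean(axis=1), selected


def _ols(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        raise ValueError("singular design in path model")
    return beta


def _paths(group, mediator, brain, covs) -> tuple[float, float, float, float]:
    n = len(group)
    ones = np.ones(n)
    x1 = np.column_stack([ones, group, covs])
    x2 = np.column_stack([ones, group, mediator, covs])
    x3 = np.column_stack([ones, group, covs])
    a = _ols(mediator, x1)[1]
    beta2 = _ols(brain, x2)
    c_prime, b = beta2[1], beta2[2]
    c_total = _ols(brain, x3)[1]
    return float(a), float(b), float(c_prime), float(c_total)


def _bc_ci(boot: np.ndarray, estimate: float, level: float = 0.95) -> tuple[float, float]:
    """Bias-corrected percentile interval (BC, no acceleration)."""
    frac = np.mean(boot < estimate)
    frac = np.clip(frac, 1e-6, 1 - 1e-6)
    z0 = stats.norm.ppf(frac)
    z = stats.norm.ppf([(1 - level) / 2, (1 + level) / 2])
    lo, hi = stats.norm.cdf(2 * z0 + z)
    return tuple(np.quantile(boot, [lo, hi]))


def fit_path_model(
    group: np.ndarray,
    mediator: np.ndarray,
    brain: np.ndarray,
    covariates: pd.DataFrame | np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    fdr_q: float = 0.05,
    ci_level: float = 0.95,
) -> PathModel:
    """Fit the two-equation path model with bootstrap inference.

    The mediator and the RMS/ICV-style continuous covariates are z-normalized
    before fitting (scale effects would otherwise make path coefficients
    incomparable across models); the a*b product is invariant to the
    mediator's scaling. Bootstrap resamples subjects with replacement.
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable bootstrap SEs")
    group = np.asarray(group, dtype=float)
    brain = np.asarray(brain, dtype=float)
    covs = np.asarray(covariates, dtype=float)
    if covs.ndim == 1:
        covs = covs[:, None]

    def z(v):
        v = np.asarray(v, dtype=float)
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    mediator = z(mediator)
    covs = np.column_stack([
        z(covs[:, j]) if len(np.unique(covs[:, j])) > 2 else covs[:, j]
        for j in range(covs.shape[1])
    ])

    a, b, c_prime, c_total = _paths(group, mediator, brain, covs)
    indirect = a * b

    rng = np.random.default_rng(seed)
    n = len(group)
    boot = np.empty((n_boot, 4))
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        boot[i] = _paths(group[idx], mediator[idx], brain[idx], covs[idx])
    boot_ab = boot[:, 0] * boot[:, 1]
    names = ["a", "b", "c_prime", "c_total"]
    se = {k: float(boot[:, j].std(ddof=1)) for j, k in enumerate(names)}
    se["indirect"] = float(boot_ab.std(ddof=1))
    est = {"a": a, "b": b, "c_prime": c_prime, "c_total": c_total}
    p = {k: float(2 * stats.norm.sf(abs(est[k] / se[k]))) for k in ("a", "b", "c_prime")}
    reject, adj = bh_fdr(np.array([p["a"], p["b"], p["c_prime"]]), q=fdr_q)
    p_adj = dict(zip(("a", "b", "c_prime"), adj.tolist()))
    ci = _bc_ci(boot_ab, indirect, ci_level)
    return PathModel(
        a=a, b=b, c_prime=c_prime, c_total=c_total, indirect=indirect,
        boot_se=se, p=p, p_adj=p_adj, ci_indirect=ci,
        significant_indirect=not (ci[0] <= 0.0 <= ci[1]),
        n_boot=n_boot, seed=seed,
    )
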