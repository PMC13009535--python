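"""Region-wise weighted linear models and BH-FDR control.

Fits the same weighted least-squares design to every region's response
(e.g. regional MSN values or regional gradient loadings), extracts the
two-sided t statistic for a named term — typically the group indicator or a
group x lifestyle interaction — and controls the false discovery rate across
regions with the Benjamini-Hochberg step-up procedure. Subject weights
default to the reciprocal of the subject's group size, which equalizes the
groups' total leverage under imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RegionalResult", "weighted_lrm", "bh_fdr", "build_design", "group_size_weights"]


@dataclass
class RegionalResult:
    """Per-region inference for one model term."""

    term: str
    t: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    significant: np.ndarray
    partial_r2: np.ndarray
    beta: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "p": self.p,
                "p_adj": self.p_adj,
                "significant": self.significant,
                "partial_r2": self.partial_r2,
                "beta": self.beta,
            }
        )


def build_design(
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "rms", "icv", "education", "income"),
    pair_interactions: tuple[tuple[str, str], ...] = (("age", "sex"), ("education", "income")),
    group_interaction: str | None = None,
) -> pd.DataFrame:
    """Design matrix: group + covariates (+ products), intercept included.

    Binary columns (group, sex) enter as 0/1; continuous columns are
    z-scored before forming any product term so interactions stay
    interpretable and the main effects centered.
    """
    def z(col: str) -> pd.Series:
        s = cohort[col].astype(float)
        if s.nunique() <= 2:
            return s
        return (s - s.mean()) / s.std()

    design = {"intercept": np.ones(len(cohort)), "group": cohort["group"].astype(float)}
    for c in covariates:
        design[c] = z(c)
    for a, b in pair_interactions:
        design[f"{a}_x_{b}"] = z(a) * z(b)
    if group_interaction is not None:
        design[f"group_x_{group_interaction}"] = (
            cohort["group"].astype(float) * z(group_interaction)
        )
    return pd.DataFrame(design, index=cohort.index)


def group_size_weights(group: np.ndarray) -> np.ndarray:
    """Reciprocal-of-group-size subject weights."""
    group = np.asarray(group)
    w = np.empty(len(group), dtype=float)
    for g in np.unique(group):
        mask = group == g
        w[mask] = 1.0 / mask.sum()
    return w


def weighted_lrm(
    responses: np.ndarray,
    design: pd.DataFrame,
    weights: np.ndarray,
    term: str,
    fdr_q: float = 0.05,
) -> RegionalResult:
    """Weighted least squares per region, inference for ``term``.

    ``responses`` is subjects x regions; the same design and weights apply to
    every region, so the WLS projector is shared and all regions are solved
    in one pass. Partial R^2 for the term is t^2 / (t^2 + df).
    """
    y = np.asarray(responses, dtype=float)
    x = design.to_numpy(dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    n, k = x.shape
    if n <= k + 2:
        raise ValueError("need more subjects than predictors + 2")
    if term not in design.columns:
        raise KeyError(f"term {term!r} not in design")
    xtwx = x.T @ (w[:, None] * x)
    rank = np.linalg.matrix_rank(xtwx)
    if rank < k:
        # name the aliased columns via the QR of the weighted design
        _, r = np.linalg.qr(np.sqrt(w)[:, None] * x)
        aliased = [design.columns[i] for i in range(k) if abs(r[i, i]) < 1e-10]
        raise ValueError(f"collinear design; aliased columns: {aliased}")
    xtwx_inv = np.linalg.inv(xtwx)
    beta = xtwx_inv @ (x.T @ (w[:, None] * y))  # k x regions
    resid = y - x @ beta
    df = n - k
    sigma2 = np.sum(w[:, None] * resid**2, axis=0) / df
    j = design.columns.get_loc(term)
    se = np.sqrt(sigma2 * xtwx_inv[j, j])
    t = beta[j] / se
    p = 2 * stats.t.sf(np.abs(t), df)
    reject, p_adj = bh_fdr(p, q=fdr_q)
    partial_r2 = t**2 / (t**2 + df)
    return RegionalResult(
        term=term, t=t, p=p, p_adj=p_adj, significant=reject,
        partial_r2=partial_r2, beta=beta[j],
    )


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: rejection flags and adjusted p-values.

    Adjusted p(i) = min_{j >= i} m * p(j) / j over the sorted p-values,
    capped at 1; the flag set is the largest i with p(i) <= i q / m and all
    smaller ranks.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    passed = ranked <= np.arange(1, m + 1) * q / m
    k = np.max(np.flatnonzero(passed)) + 1 if passed.any() else 0
    reject_sorted = np.zeros(m, dtype=bool)
    reject_sorted[:k] = True
    reject = np.empty(m, dtype=bool)
    p_adj = np.empty(m, dtype=float)
    reject[order] = reject_sorted
    p_adj[order] = adj
    return reject, p_adj
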