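"""Differential-stability filtering and PLS alignment of gene expression
with a cortical effect map.

For a univariate response the first PLS component has a closed form: the
gene weight vector is proportional to X^T y for column-z-scored X and
z-scored y, and the regional scores are X w. Variance explained by PLS1 is
the squared correlation between the response and the scores (an identity for
a univariate response). Significance of that variance uses the spin null
from :mod:`connvar.spatial`; per-gene estimation error uses a
parcel-resampling bootstrap whose component sign is re-aligned to the
full-sample solution before the SE is taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spatial import spin_permutations
from .synthdata import ParcelGeometry

__all__ = [
    "PLSResult",
    "differential_stability",
    "pls1",
    "pls_significance",
    "bootstrap_gene_z",
    "gene_set_overlap",
]


@dataclass
class PLSResult:
    """First PLS component of expression against a brain map."""

    gene_weights: pd.Series
    scores: np.ndarray
    variance_explained: float
    permutation_p: float | None = None
    gene_z: pd.Series | None = None
    gene_se: pd.Series | None = None
    pls1_pos: list[str] | None = None
    pls1_neg: list[str] | None = None


def differential_stability(
    expr_by_donor: dict[str, pd.DataFrame], threshold: float = 0.1
) -> tuple[pd.Series, list[str]]:
    """Per-gene differential stability and the retained gene list.

    DS is the mean over donor pairs of the Spearman rank correlation of the
    gene's regional expression profile; genes with DS strictly above
    ``threshold`` are retained (default 0.1; 0 and 0.2 are the usual
    sensitivity alternates).
    """
    donors = list(expr_by_donor.values())
    if len(donors) < 2:
        raise ValueError("differential stability needs at least 2 donors")
    genes = donors[0].columns
    ranks = [d[genes].rank(axis=0).to_numpy() for d in donors]
    n_parcels = ranks[0].shape[0]
    if n_parcels < 3:
        raise ValueError("need at least 3 shared parcels")
    corrs = []
    for i in range(len(ranks)):
        for j in range(i + 1, len(ranks)):
            a = ranks[i] - ranks[i].mean(axis=0)
            b = ranks[j] - ranks[j].mean(axis=0)
            num = (a * b).sum(axis=0)
            den = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
            corrs.append(num / den)
    ds = pd.Series(np.mean(corrs, axis=0), index=genes, name="DS")
    retained = list(ds.index[ds > threshold])
    return ds, retained


def _znorm(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def pls1(expr: pd.DataFrame | np.ndarray, response: np.ndarray) -> PLSResult:
    """First PLS component of (z-normalized) expression vs a brain map.

    Sign convention: the regional scores correlate non-negatively with the
    response (automatic for the closed form w proportional to X^T y).
    """
    if isinstance(expr, pd.DataFrame):
        genes = expr.columns
        x = expr.to_numpy(dtype=float)
    else:
        x = np.asarray(expr, dtype=float)
        genes = pd.RangeIndex(x.shape[1])
    y = np.asarray(response, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 parcels")
    if x.shape[0] != y.size:
        raise ValueError("expression and response must share parcels")
    xz = _znorm(x)
    yz = (y - y.mean()) / y.std()
    w = xz.T @ yz
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("response is orthogonal to every gene")
    w = w / norm
    scores = xz @ w
    r = np.corrcoef(yz, scores)[0, 1]
    return PLSResult(
        gene_weights=pd.Series(w, index=genes, name="pls1_weight"),
        scores=scores,
        variance_explained=float(r**2),
    )


def pls_significance(
    expr: pd.DataFrame | np.ndarray,
    response: np.ndarray,
    geometry: ParcelGeometry,
    n_perm: int = 1000,
    seed: int = 0,
    permutations: np.ndarray | None = None,
) -> float:
    """Spin-permutation p for the variance explained by PLS1.

    The response map is spin-rotated ``n_perm`` times, PLS1 refit, and p is
    the proportion of null variance-explained values >= the observed one.
    """
    observed = pls1(expr, response).variance_explained
    if permutations is None:
        permutations = spin_permutations(geometry, n_perm, seed)
    y = np.asarray(response, dtype=float)
    null_ve = np.array(
        [pls1(expr, y[idx]).variance_explained for idx in permutations]
    )
    return float(np.mean(null_ve >= observed))


def bootstrap_gene_z(
    expr: pd.DataFrame,
    response: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    z_threshold: float = 5.0,
    max_retries: int = 100,
) -> PLSResult:
    """Bootstrap PLS1 gene ranking and the signed high-confidence gene sets.

    Parcels (rows) are resampled with replacement; each refit component is
    sign-aligned to the full-sample component (correlation of weight vectors
    >= 0) before the bootstrap SE is computed. Z = full-sample weight / SE;
    genes with Z above +``z_threshold`` form the positive set, below
    -``z_threshold`` the negative set. Degenerate resamples (constant
    response) are redrawn, with a bounded number of retries.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    full = pls1(expr, response)
    x = expr.to_numpy(dtype=float) if isinstance(expr, pd.DataFrame) else np.asarray(expr)
    y = np.asarray(response, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    w_full = full.gene_weights.to_numpy()
    boot = np.empty((n_boot, x.shape[1]))
    for i in range(n_boot):
        for attempt in range(max_retries):
            idx = rng.integers(0, n, n)
            if np.std(y[idx]) > 0:
                break
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        w = pls1(x[idx], y[idx]).gene_weights.to_numpy()
        if w @ w_full < 0:
            w = -w
        boot[i] = w
    se = boot.std(axis=0, ddof=1)
    se = np.where(se == 0, np.nan, se)
    z = w_full / se
    genes = full.gene_weights.index
    z_series = pd.Series(z, index=genes, name="Z")
    full.gene_se = pd.Series(se, index=genes, name="boot_se")
    full.gene_z = z_series
    full.pls1_pos = list(genes[z_series > z_threshold])
    full.pls1_neg = list(genes[z_series < -z_threshold])
    return full


def gene_set_overlap(genes_a, genes_b) -> list[str]:
    """Plain set intersection of two gene lists, input order of the first."""
    b = set(genes_b)
    return [g for g in genes_a if g in b]
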