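"""Morphometric similarity networks.

An MSN edge is the Pearson correlation between two parcels' z-normalized
morphometric feature vectors (cortical thickness, gray matter volume,
surface area, Gaussian curvature, mean curvature). With only 5 features the
per-edge correlation is intrinsically noisy — |r| = 1 for collinear vectors
is a legitimate value here, not an error — but averaged regionally the
network carries a stable structural similarity profile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import ConnMatrix

__all__ = ["build_msn", "regional_msn"]


def build_msn(features: pd.DataFrame | np.ndarray) -> ConnMatrix:
    """Parcels x parcels correlation of z-scored regional feature vectors.

    Each feature column is z-normalized across parcels (within subject), then
    every pair of parcel 5-vectors is Pearson-correlated. Diagonal is zeroed
    by the shared connectivity-matrix convention.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        names = [f"feature_{i}" for i in range(x.shape[1])]
    if x.shape[0] < 3:
        raise ValueError("need at least 3 parcels")
    sd = x.std(axis=0)
    bad = [names[i] for i in np.flatnonzero(sd == 0)]
    if bad:
        raise ValueError(f"zero-variance feature(s) across parcels: {bad}")
    z = (x - x.mean(axis=0)) / sd
    r = np.corrcoef(z)
    np.fill_diagonal(r, 0.0)
    return ConnMatrix(r)


def regional_msn(msn: ConnMatrix) -> np.ndarray:
    """Per-parcel mean of off-diagonal MSN row entries."""
    v = msn.values
    n = v.shape[0]
    return (v.sum(axis=1) - np.diag(v)) / (n - 1)
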