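"""Frame censoring, global-signal regression, RSFC, gradients, label maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthdata import RunTimeSeries

__all__ = [
    "ConnMatrix",
    "GradientMap",
    "censor_frames",
    "regress_global_signal",
    "compute_rsfc",
    "principal_gradient",
    "dice_overlap",
    "fuse_parcellations",
    "pairwise_parcellation_agreement",
    "FISHER_Z_CLIP",
]

#: |r| is clipped here before arctanh; arctanh(+-1) diverges.
FISHER_Z_CLIP = 1.0 - 1e-7


@dataclass
class ConnMatrix:
    """Symmetric parcels x parcels Fisher-z connectivity, zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        self.values = v

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass
class GradientMap:
    """First principal axis of a connectivity matrix, one loading per parcel."""

    values: np.ndarray
    variance_explained: float


def censor_frames(
    rms: np.ndarray, threshold: float = 0.2, min_segment: int = 5
) -> tuple[np.ndarray, bool]:
    """Motion-censoring mask for one run.

    Frames with RMS above ``threshold`` are censored together with the one
    frame immediately preceding and the two frames following each spike; any
    remaining uncensored contiguous segment shorter than ``min_segment``
    frames is then censored as well. The run is invalid when more than half
    of its frames end up censored.

    Returns ``(censored_mask, run_valid)``.
    """
    rms = np.asarray(rms, dtype=float)
    if rms.size == 0:
        raise ValueError("rms trace is empty")
    if np.any(rms < 0):
        raise ValueError("rms values must be non-negative")
    n = rms.size
    censored = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(rms > threshold):
        censored[max(i - 1, 0) : min(i + 3, n)] = True
    # sweep for short surviving segments
    i = 0
    while i < n:
        if censored[i]:
            i += 1
            continue
        j = i
        while j < n and not censored[j]:
            j += 1
        if j - i < min_segment:
            censored[i:j] = True
        i = j
    run_valid = censored.sum() <= n / 2
    return censored, run_valid


def _run_valid(run: RunTimeSeries) -> bool:
    return run.censored.sum() <= len(run.censored) / 2


def regress_global_signal(run: RunTimeSeries) -> RunTimeSeries:
    """Regress the global signal and its first derivative out of a run.

    The global signal is the across-parcel mean of each frame; its derivative
    is the backward difference (first element 0). The regression, including
    an intercept, is fitted on uncensored frames only; censored frames are
    passed through untouched (they stay flagged and are excluded downstream).
    """
    keep = ~run.censored
    if not _run_valid(run):
        raise ValueError("run invalid: more than half the frames are censored")
    if keep.sum() < 3:
        raise ValueError("need at least 3 uncensored frames")
    data = np.asarray(run.data, dtype=float)
    global_sig = data.mean(axis=1)
    deriv = np.empty_like(global_sig)
    deriv[0] = 0.0
    deriv[1:] = np.diff(global_sig)
    design = np.column_stack([global_sig, deriv, np.ones(len(global_sig))])
    x = design[keep]
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient global-signal regressors")
    beta, *_ = np.linalg.lstsq(x, data[keep], rcond=None)
    out = data.copy()
    out[keep] = data[keep] - x @ beta
    return RunTimeSeries(
        data=out, rms=run.rms.copy(), censored=run.censored.copy(), run_id=run.run_id
    )


def compute_rsfc(runs: list[RunTimeSeries]) -> ConnMatrix:
    """Fisher-z RSFC: per-run Pearson correlation over uncensored frames,
    arctanh with |r| clipped at ``FISHER_Z_CLIP``, averaged across valid
    runs; diagonal set to 0."""
    valid = [r for r in runs if _run_valid(r)]
    if not valid:
        raise ValueError("no valid runs")
    mats = []
    for run in valid:
        x = np.asarray(run.data, dtype=float)[~run.censored]
        sd = x.std(axis=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(f"zero-variance parcel(s) in run {run.run_id!r}: {bad.tolist()}")
        r = np.corrcoef(x, rowvar=False)
        z = np.arctanh(np.clip(r, -FISHER_Z_CLIP, FISHER_Z_CLIP))
        mats.append(z)
    z_mean = np.mean(mats, axis=0)
    z_mean = (z_mean + z_mean.T) / 2
    np.fill_diagonal(z_mean, 0.0)
    return ConnMatrix(z_mean)


def _threshold_top(values: np.ndarray, fraction: float) -> np.ndarray:
    """Keep the top ``fraction`` of entries per row, re-symmetrize by max."""
    n = values.shape[0]
    k = max(int(round(fraction * n)), 1)
    out = np.zeros_like(values)
    for i in range(n):
        idx = np.argpartition(values[i], -k)[-k:]
        out[i, idx] = values[i, idx]
    return np.maximum(out, out.T)


def principal_gradient(
    conn: ConnMatrix,
    threshold_top_fraction: float | None = None,
    reference: np.ndarray | None = None,
) -> GradientMap:
    """First principal component of a connectivity matrix.

    Rows are treated as observations (one connectivity profile per parcel)
    and columns are centered; the loadings are the projection of each profile
    on the first principal axis, so the map assigns one value per parcel.
    ``variance_explained`` is the first eigenvalue over the trace of the
    centered covariance. Optional row-wise top-fraction thresholding (with
    max re-symmetrization) reproduces the sparsified variant. The loading
    sign is aligned so the correlation with ``reference`` (when given) is
    non-negative; PCA alone leaves it arbitrary.
    """
    x = conn.values.copy()
    if threshold_top_fraction is not None:
        if not 0 < threshold_top_fraction <= 1:
            raise ValueError("threshold_top_fraction must be in (0, 1]")
        x = _threshold_top(x, threshold_top_fraction)
    xc = x - x.mean(axis=0, keepdims=True)
    if not np.any(xc):
        raise ValueError("constant connectivity matrix has no principal gradient")
    cov = xc.T @ xc / max(x.shape[0] - 1, 1)
    eigval, eigvec = np.linalg.eigh(cov)
    first = eigvec[:, -1]
    loadings = xc @ first
    var_exp = float(eigval[-1] / np.trace(cov))
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        if np.corrcoef(loadings, ref)[0, 1] < 0:
            loadings = -loadings
    return GradientMap(values=loadings, variance_explained=var_exp)


def dice_overlap(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Mean Dice coefficient over labels: 2|A∩B| / (|A| + |B|).

    Labels absent from both maps are skipped.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label maps must have equal length")
    labels = np.union1d(np.unique(a), np.unique(b))
    scores = []
    for lab in labels:
        in_a = a == lab
        in_b = b == lab
        denom = in_a.sum() + in_b.sum()
        if denom == 0:
            continue
        scores.append(2.0 * np.sum(in_a & in_b) / denom)
    return float(np.mean(scores))


def fuse_parcellations(label_maps: list[np.ndarray]) -> np.ndarray:
    """Maximum-probability fusion: per-vertex modal label, ties to the
    lowest label id."""
    if not label_maps:
        raise ValueError("need at least one label map")
    stack = np.vstack([np.asarray(m) for m in label_maps])
    if not np.all([m.shape == stack[0].shape for m in stack]):
        raise ValueError("label maps must have equal length")
    n_vertices = stack.shape[1]
    fused = np.empty(n_vertices, dtype=stack.dtype)
    for v in range(n_vertices):
        labels, counts = np.unique(stack[:, v], return_counts=True)
        fused[v] = labels[np.argmax(counts)]  # unique() sorts: ties -> lowest
    return fused


def pairwise_parcellation_agreement(
    maps_group_a: list[np.ndarray], maps_group_b: list[np.ndarray]
) -> np.ndarray:
    """Per-vertex fraction of cross-group pairs sharing the vertex label,
    averaged over all |A| x |B| pairs."""
    if not maps_group_a or not maps_group_b:
        raise ValueError("each group needs at least one map")
    a = np.vstack(maps_group_a)
    b = np.vstack(maps_group_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("label maps must have equal length")
    n_vertices = a.shape[1]
    out = np.empty(n_vertices)
    for v in range(n_vertices):
        labels = np.union1d(a[:, v], b[:, v])
        count_a = np.array([(a[:, v] == lab).sum() for lab in labels])
        count_b = np.array([(b[:, v] == lab).sum() for lab in labels])
        out[v] = (count_a * count_b).sum() / (a.shape[0] * b.shape[0])
    return out
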