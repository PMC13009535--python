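"""Seeded synthetic cohorts, time series, morphometry, and gene expression.

Every generator here is a pure function of its configuration and seed: the
planted structure (a smooth connectivity effect along a synthetic
sensorimotor-association axis, group-correlated lifestyle scores, a
group -> mediator -> brain path, and expression maps aligned with the effect
map) is exactly what the downstream analysis stages are built to recover, so
the generators double as the ground truth for the recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SynthConfig",
    "ParcelGeometry",
    "RunTimeSeries",
    "make_geometry",
    "generate_cohort",
    "generate_timeseries",
    "generate_morphometry",
    "generate_expression",
    "generate_mediation_dataset",
    "planted_connectivity_effect",
    "smooth_fields",
    "LIFESTYLE_FACTORS",
]

#: Lifestyle factors and their default point-biserial correlation with the
#: binary group label (group coded 1 for the smaller group A).
LIFESTYLE_FACTORS: Mapping[str, float] = {
    "education": -0.15,
    "income": -0.23,
    "substance_use": -0.08,
    "sleep": 0.11,
    "physical_activity": -0.18,
    "social": -0.08,
}


class ConfigError(ValueError):
    """Raised for invalid synthetic-data configurations."""


@dataclass(frozen=True)
class SynthConfig:
    """Configuration for all synthetic generators.

    Defaults are desk-scale: 100 parcels in 7 networks, a 60 + 240 cohort
    (preserving a roughly 1:4 group imbalance), and 2 runs of 300 frames per
    subject.
    """

    n_group_a: int = 60
    n_group_b: int = 240
    n_parcels: int = 100
    n_networks: int = 7
    n_runs: int = 2
    frames_per_run: int = 300
    effect_axis_strength: float = 0.6
    mediation_a: float = 0.5
    mediation_b: float = 0.4
    direct_c: float = 0.2
    expr_genes: int = 500
    expr_spatial_scale: float = 0.5
    seed: int = 0
    # secondary knobs (kept out of the main signature of the study design)
    lifestyle_group_corr: Mapping[str, float] = field(
        default_factory=lambda: dict(LIFESTYLE_FACTORS)
    )
    subject_factor_sd: float = 0.08
    rms_spike_prob: float = 0.03
    morph_effect_strength: float = 0.8
    expr_loading_frac: float = 0.10
    expr_loading_strength: float = 1.0

    def __post_init__(self) -> None:
        counts = {
            "n_group_a": self.n_group_a,
            "n_group_b": self.n_group_b,
            "n_parcels": self.n_parcels,
            "n_networks": self.n_networks,
            "n_runs": self.n_runs,
            "frames_per_run": self.frames_per_run,
            "expr_genes": self.expr_genes,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        if self.n_group_a + self.n_group_b < 10:
            raise ConfigError("total cohort size must be at least 10")
        if self.n_networks > self.n_parcels:
            raise ConfigError("n_networks cannot exceed n_parcels")
        for name in ("effect_axis_strength", "mediation_a", "mediation_b", "direct_c"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)

    def rng(self, *stream: int) -> np.random.Generator:
        """Independent generator for a named sub-stream of the master seed."""
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, *stream])


@dataclass(frozen=True)
class ParcelGeometry:
    """Parcel metadata: network labels, hemisphere, and spherical centroids.

    ``axis_rank`` is the parcel's normalized position in [0, 1] along the
    synthetic sensorimotor-association hierarchy; the planted connectivity
    effect is smooth in this coordinate.
    """

    parcel_id: np.ndarray
    network: np.ndarray
    hemisphere: np.ndarray
    centroid: np.ndarray
    axis_rank: np.ndarray

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_id": self.parcel_id,
                "network": self.network,
                "hemisphere": self.hemisphere,
                "x": self.centroid[:, 0],
                "y": self.centroid[:, 1],
                "z": self.centroid[:, 2],
                "axis_rank": self.axis_rank,
            }
        )


@dataclass
class RunTimeSeries:
    """One fMRI run: frames x parcels signal plus per-frame motion."""

    data: np.ndarray
    rms: np.ndarray
    censored: np.ndarray
    run_id: str = ""

    def __post_init__(self) -> None:
        if not (len(self.data) == len(self.rms) == len(self.censored)):
            raise ValueError("data, rms and censored must have equal length")


def _fibonacci_hemisphere(n: int, sign: float, phase: float) -> np.ndarray:
    """Near-uniform points on the unit sphere folded onto one hemisphere.

    ``sign`` fixes the hemisphere (x < 0 for L, x > 0 for R); ``phase``
    decorrelates the two lattices so hemispheres are not mirror images.
    """
    i = np.arange(n)
    golden = (1 + np.sqrt(5)) / 2
    z = 1 - 2 * (i + 0.5) / n
    theta = 2 * np.pi * ((i / golden + phase) % 1.0)
    r = np.sqrt(np.maximum(0.0, 1 - z**2))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    pts[:, 0] = sign * np.abs(pts[:, 0])
    # renormalize defensively (|x| fold keeps unit norm, but be exact)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def make_geometry(cfg: SynthConfig) -> ParcelGeometry:
    """Place parcel centroids on the unit sphere and assign networks.

    Centroids use a Fibonacci lattice per hemisphere (near-uniform coverage,
    which the spin null relies on). The hierarchy coordinate is the polar
    angle from the "sensorimotor pole" (0, 0, 1), rank-normalized to span
    [0, 1] exactly; networks are contiguous quantile bins of that rank.
    """
    n = cfg.n_parcels
    n_left = n // 2 + n % 2
    n_right = n - n_left
    left = _fibonacci_hemisphere(n_left, -1.0, 0.0)
    right = _fibonacci_hemisphere(max(n_right, 1), +1.0, 0.37)[:n_right]
    centroid = np.vstack([left, right]) if n_right else left
    hemisphere = np.array(["L"] * n_left + ["R"] * n_right)
    polar = np.arccos(np.clip(centroid[:, 2], -1, 1))
    order = np.argsort(polar, kind="stable")
    rank = np.empty(n)
    rank[order] = np.arange(n)
    axis_rank = rank / (n - 1) if n > 1 else np.zeros(1)
    network = np.minimum((axis_rank * cfg.n_networks).astype(int), cfg.n_networks - 1) + 1
    return ParcelGeometry(
        parcel_id=np.arange(n),
        network=network,
        hemisphere=hemisphere,
        centroid=centroid,
        axis_rank=axis_rank,
    )


def _copula_rho(target_r: float, p: float) -> float:
    """Latent Gaussian correlation giving point-biserial ``target_r``.

    With group = 1{z > c}, c = Phi^-1(1 - p), and x = rho * z + noise,
    corr(group, x) = rho * phi(c) / sqrt(p (1 - p)); invert for rho.
    """
    c = stats.norm.ppf(1 - p)
    rho = target_r * np.sqrt(p * (1 - p)) / stats.norm.pdf(c)
    if abs(rho) >= 1:
        raise ConfigError(f"group correlation {target_r} unattainable at p={p:.3f}")
    return rho


def generate_cohort(cfg: SynthConfig) -> pd.DataFrame:
    """Two-group cohort with family structure and group-linked lifestyle.

    Returns one row per subject with columns: subject_id, family_id, group
    (1 = group A, the smaller group), age (years), sex (0/1), rms (mean
    framewise RMS, mm), icv, and the six lifestyle composites. Lifestyle
    scores are induced through a Gaussian copula so their point-biserial
    correlation with the group label hits the configured targets exactly in
    expectation.
    """
    rng = cfg.rng(1)
    n_a, n_b = cfg.n_group_a, cfg.n_group_b
    n = n_a + n_b
    p = n_a / n

    # latent group propensity; top-n_a ranks form group A (exact sizes)
    z = rng.standard_normal(n)
    group = np.zeros(n, dtype=int)
    group[np.argsort(z)[::-1][:n_a]] = 1

    lifestyle = {}
    for name in LIFESTYLE_FACTORS:
        target = cfg.lifestyle_group_corr.get(name, 0.0)
        rho = _copula_rho(target, p) if target else 0.0
        lifestyle[name] = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(n)

    age = rng.uniform(22, 37, n)
    sex = rng.integers(0, 2, n)
    rms = np.abs(rng.normal(0.08, 0.02, n)) + 1e-4
    icv = rng.normal(1500, 130, n) + 90 * sex

    # families of size 1-3, nested within group so split constraints bind
    family_id = np.empty(n, dtype=object)
    fam = 0
    for g in (0, 1):
        idx = np.flatnonzero(group == g)
        pos = 0
        while pos < len(idx):
            size = min(int(rng.choice([1, 2, 3], p=[0.6, 0.25, 0.15])), len(idx) - pos)
            for j in idx[pos : pos + size]:
                family_id[j] = f"F{fam:05d}"
            fam += 1
            pos += size

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "family_id": family_id,
            "group": group,
            "age": age,
            "sex": sex,
            "rms": rms,
            "icv": icv,
            **lifestyle,
        }
    )
    return df


def _latent_model(geometry: ParcelGeometry, cfg: SynthConfig):
    """Shared low-rank base covariance and the axis-weighted group shift."""
    rng = cfg.rng(2)
    n = geometry.n_parcels
    k = 5
    loadings = rng.normal(0.0, 0.35, (n, k))
    base_cov = loadings @ loadings.T + np.eye(n)
    # group A carries an extra axis-aligned rank-1 component: PSD by
    # construction, so subject covariances stay positive definite. The
    # asymmetric offset keeps the sensorimotor pole sign-opposed to the
    # association pole without making the regional row means degenerate.
    v = geometry.axis_rank - 0.25
    delta = cfg.effect_axis_strength * np.outer(v, v)
    return loadings, base_cov, delta


def _to_corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def _gsr_residual_cov(cov: np.ndarray) -> np.ndarray:
    """Population covariance after regression on the global signal and its
    backward-difference derivative (frames i.i.d.)."""
    n = cov.shape[0]
    ones = np.ones(n)
    c_g = cov @ ones / n  # cov(x_t, g_t); also equals cov(x_t, g_t - g_{t-1})
    s = ones @ cov @ ones / n**2  # var(g)
    c = np.column_stack([c_g, c_g])
    a = np.array([[s, s], [s, 2 * s]])
    return cov - c @ np.linalg.solve(a, c.T)


def planted_connectivity_effect(
    geometry: ParcelGeometry, cfg: SynthConfig, gsr: bool = True
):
    """Ground-truth group difference of population connectivity.

    The planted maps are the population-level group difference of exactly
    the quantity the preprocessing stage estimates: the correlation matrix
    of the (optionally global-signal-regressed) latent process. Returns
    ``(edgewise, regional)`` — the edgewise difference (group A minus
    group B, zero diagonal) and its per-parcel row mean, the maps the
    recovery tests compare against.
    """
    loadings, base_cov, delta = _latent_model(geometry, cfg)
    # expected covariance over the subject loading jitter inflates the
    # diagonal by k * sd^2 (E[L_i L_i^T] = L L^T + k sd^2 I)
    base_cov = base_cov + loadings.shape[1] * cfg.subject_factor_sd**2 * np.eye(
        geometry.n_parcels
    )
    cov_a, cov_b = _to_corr(base_cov + delta), _to_corr(base_cov)
    if gsr:
        cov_a, cov_b = _gsr_residual_cov(cov_a), _gsr_residual_cov(cov_b)
    clip = 1.0 - 1e-7  # same Fisher-z clipping convention as the estimator
    diff = np.arctanh(np.clip(_to_corr(cov_a), -clip, clip)) - np.arctanh(
        np.clip(_to_corr(cov_b), -clip, clip)
    )
    np.fill_diagonal(diff, 0.0)
    n = geometry.n_parcels
    regional = diff.sum(axis=1) / max(n - 1, 1)
    return diff, regional


def generate_timeseries(
    cohort: pd.DataFrame, geometry: ParcelGeometry, cfg: SynthConfig
) -> dict[str, list[RunTimeSeries]]:
    """Per-subject multi-run time series with planted group connectivity.

    Each subject's latent covariance is the shared low-rank base plus, for
    group-A subjects, the axis-weighted rank-1 group component, plus a
    subject-specific jitter of the factor loadings (positive definite by
    construction). Frames are i.i.d. draws from that multivariate normal.
    The RMS trace hovers near the subject's mean motion with occasional
    spikes above 0.2 mm; the returned ``censored`` masks are all-False (frame
    censoring is the job of the preprocessing stage).
    """
    if cfg.frames_per_run < 10:
        raise ConfigError("frames_per_run must be at least 10")
    loadings, _, delta = _latent_model(geometry, cfg)
    n_parcels = geometry.n_parcels
    out: dict[str, list[RunTimeSeries]] = {}
    for row_i, row in enumerate(cohort.itertuples(index=False)):
        rng = cfg.rng(3, row_i)
        l_subj = loadings + rng.normal(0.0, cfg.subject_factor_sd, loadings.shape)
        cov = l_subj @ l_subj.T + np.eye(n_parcels) + (row.group == 1) * delta
        chol = np.linalg.cholesky(_to_corr(cov))
        runs = []
        for r in range(cfg.n_runs):
            frames = rng.standard_normal((cfg.frames_per_run, n_parcels)) @ chol.T
            rms = np.abs(rng.normal(row.rms, 0.02, cfg.frames_per_run)) + 1e-4
            spikes = rng.random(cfg.frames_per_run) < cfg.rms_spike_prob
            rms[spikes] += rng.uniform(0.15, 0.35, spikes.sum())
            runs.append(
                RunTimeSeries(
                    data=frames,
                    rms=rms,
                    censored=np.zeros(cfg.frames_per_run, dtype=bool),
                    run_id=f"{row.subject_id}_run{r + 1}",
                )
            )
        out[row.subject_id] = runs
    return out


MORPH_FEATURES = (
    "cortical_thickness",
    "gray_matter_volume",
    "surface_area",
    "gaussian_curvature",
    "mean_curvature",
)


def smooth_fields(
    geometry: ParcelGeometry,
    scale: float,
    rng: np.random.Generator,
    n_fields: int = 1,
) -> np.ndarray:
    """Draw spatially autocorrelated fields on the sphere (n_fields x parcels).

    Gaussian-process samples with squared-exponential kernel in chordal
    distance; ``scale`` -> 0 degenerates to white noise.
    """
    x = geometry.centroid
    if scale <= 1e-6:
        return rng.standard_normal((n_fields, geometry.n_parcels))
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    kernel = np.exp(-d2 / (2 * scale**2)) + 1e-8 * np.eye(geometry.n_parcels)
    chol = np.linalg.cholesky(kernel)
    return rng.standard_normal((n_fields, geometry.n_parcels)) @ chol.T


def generate_morphometry(
    cohort: pd.DataFrame, geometry: ParcelGeometry, cfg: SynthConfig
) -> dict[str, pd.DataFrame]:
    """Per-subject parcels x 5 morphometric feature tables.

    Group effects are co-localized with the planted connectivity effect: each
    feature's group shift is proportional to the regional planted map, so the
    morphometric-similarity group contrast lands on the same cortical axis as
    the connectivity contrast.
    """
    rng = cfg.rng(4)
    _, regional = planted_connectivity_effect(geometry, cfg)
    scale = np.std(regional)
    effect_map = regional / scale if scale > 0 else regional
    base = smooth_fields(geometry, 0.6, rng, n_fields=len(MORPH_FEATURES))
    feat_sign = rng.choice([-1.0, 1.0], len(MORPH_FEATURES))
    out = {}
    for row_i, row in enumerate(cohort.itertuples(index=False)):
        srng = cfg.rng(4, 1 + row_i)
        g = 1.0 if row.group == 1 else 0.0
        values = (
            base
            + g * cfg.morph_effect_strength * feat_sign[:, None] * effect_map[None, :]
            + srng.normal(0.0, 0.6, base.shape)
        )
        out[row.subject_id] = pd.DataFrame(
            values.T, columns=list(MORPH_FEATURES), index=geometry.parcel_id
        )
    return out


@dataclass
class ExpressionResult:
    """Synthetic region x gene expression with optional pseudo-donors."""

    expression: pd.DataFrame
    by_donor: dict[str, pd.DataFrame]
    loaded_genes: list[str]
    loaded_signs: np.ndarray | None = None


def generate_expression(
    geometry: ParcelGeometry,
    effect_map: np.ndarray,
    cfg: SynthConfig,
    n_donors: int = 1,
    donor_noise: float = 0.5,
) -> ExpressionResult:
    """Spatially autocorrelated expression with a planted effect-map loading.

    A configurable fraction of genes carries a loading on the (z-scored)
    effect map on top of a smooth spatial field; the rest are pure smooth
    fields. With ``n_donors > 1`` each pseudo-donor observes the shared map
    plus donor-specific smooth noise, for differential-stability testing.
    """
    if cfg.expr_genes < 2:
        raise ConfigError("expr_genes must be at least 2")
    effect_map = np.asarray(effect_map, dtype=float)
    if effect_map.shape != (geometry.n_parcels,):
        raise ConfigError("effect_map must have one value per parcel")
    rng = cfg.rng(5)
    g = cfg.expr_genes
    n_loaded = int(round(cfg.expr_loading_frac * g))
    z_eff = (effect_map - effect_map.mean()) / effect_map.std()
    fields = smooth_fields(geometry, cfg.expr_spatial_scale, rng, n_fields=g)
    signs = rng.choice([-1.0, 1.0], n_loaded)
    fields[:n_loaded] += cfg.expr_loading_strength * signs[:, None] * z_eff[None, :]
    genes = [f"G{i:05d}" for i in range(g)]
    shared = pd.DataFrame(fields.T, columns=genes, index=geometry.parcel_id)
    by_donor = {}
    for d in range(n_donors):
        noise = smooth_fields(geometry, cfg.expr_spatial_scale, cfg.rng(5, 1 + d), g)
        by_donor[f"D{d + 1}"] = shared + donor_noise * noise.T
    agg = sum(by_donor.values()) / n_donors if n_donors > 1 else shared
    return ExpressionResult(
        expression=agg,
        by_donor=by_donor,
        loaded_genes=genes[:n_loaded],
        loaded_signs=signs,
    )


def generate_mediation_dataset(
    cfg: SynthConfig, n: int | None = None
) -> pd.DataFrame:
    """Group, mediator, brain score and covariates with planted paths.

    mediator = a * group + covariate effects + noise
    brain    = c' * group + b * mediator + covariate effects + noise

    so the planted indirect effect is exactly ``mediation_a * mediation_b``
    and the total group effect is ``direct_c + mediation_a * mediation_b``.
    The product a*b is invariant to the z-normalization of the mediator the
    fitting stage applies.
    """
    rng = cfg.rng(6)
    if n is None:
        n = cfg.n_group_a + cfg.n_group_b
    p = cfg.n_group_a / (cfg.n_group_a + cfg.n_group_b)
    group = (rng.random(n) < p).astype(float)
    age = rng.uniform(22, 37, n)
    sex = rng.integers(0, 2, n).astype(float)
    rms = np.abs(rng.normal(0.08, 0.02, n)) + 1e-4
    icv = rng.normal(1500, 130, n) + 90 * sex
    age_z = (age - age.mean()) / age.std()
    mediator = (
        cfg.mediation_a * group + 0.1 * age_z + rng.standard_normal(n)
    )
    brain = (
        cfg.direct_c * group
        + cfg.mediation_b * mediator
        + 0.1 * sex
        + rng.standard_normal(n)
    )
    return pd.DataFrame(
        {
            "subject_id": [f"M{i:05d}" for i in range(n)],
            "group": group.astype(int),
            "mediator": mediator,
            "brain": brain,
            "age": age,
            "sex": sex.astype(int),
            "rms": rms,
            "icv": icv,
        }
    )
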