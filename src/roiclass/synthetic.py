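"""Synthetic multi-site ROI cohort generator with known ground truth.

Feature values follow the additive/multiplicative site-effect model that
location/scale harmonization assumes:

    y_ijg = alpha_g + beta_age * age_ij / 10 + beta_sex * sex_ij
            + d * sigma_g * 1[case_ij] * 1[g in affected]
            + gamma_ig + delta_ig * eps_ijg,        eps ~ N(0, sigma_g^2)

with per-site feature shifts gamma_ig ~ N(Gamma_i, tau2_i) and scale factors
delta_ig^2 ~ InvGamma(shape_i, rate_i). Case/control group differences are
expressed in within-group SD units (Cohen's d) on a designated affected ROI
subset, so power statements are scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import GROUPS, META_COLUMNS, ROICohort
from .schemas import FeatureSchema


class ConfigError(ValueError):
    """Raised for inconsistent generator configurations."""


def _per_site(value, n_sites: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_sites, float(arr))
    if arr.shape != (n_sites,):
        raise ConfigError(f"{name} must be a scalar or a length-{n_sites} vector")
    return arr


def _per_feature(value, n_features: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_features, float(arr))
    if arr.shape != (n_features,):
        raise ConfigError(f"{name} must be a scalar or a length-{n_features} vector")
    return arr


@dataclass
class GeneratorConfig:
    """Everything needed to draw one reproducible multi-site cohort.

    ``site_scale_shape=None`` fixes every delta at 1 (no multiplicative site
    effect); ``site_location_var=0`` makes gamma deterministic at the site
    prior mean, so zero prior mean + unit scale collapses to one-site data.
    """

    schema: FeatureSchema
    n_sites: int = 1
    n_per_site: Mapping[str, int] = field(default_factory=lambda: {"HC": 50, "TLE-HS-L": 50})
    affected_rois: Sequence[str] = ()
    effect_size: float = 0.0
    baseline: float | Sequence[float] = 0.45  # alpha_g, loosely FA-like
    noise_sd: float | Sequence[float] = 0.03  # sigma_g
    beta_age: float = 0.0  # per decade of age
    beta_sex: float = 0.0
    site_location_mean: float | Sequence[float] = 0.0  # Gamma_i
    site_location_var: float | Sequence[float] = 0.0  # tau2_i
    site_scale_shape: float | Sequence[float] | None = None  # inv-gamma shape
    site_scale_rate: float | Sequence[float] = 1.0  # inv-gamma rate
    age_range: tuple[float, float] = (18.0, 70.0)
    sex_ratio: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.schema)
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if not self.n_per_site:
            raise ConfigError("n_per_site must name at least one group")
        for group, count in self.n_per_site.items():
            if group not in GROUPS:
                raise ConfigError(f"unknown group {group!r}")
            if count < 1:
                raise ConfigError(f"sample size for {group!r} must be >= 1")
        unknown = set(self.affected_rois) - set(f.roi_name for f in self.schema)
        if unknown:
            raise ConfigError(f"affected ROIs not in schema: {sorted(unknown)}")
        if self.effect_size < 0:
            raise ConfigError("effect size d must be >= 0")
        if np.any(_per_feature(self.noise_sd, n, "noise_sd") <= 0):
            raise ConfigError("noise_sd must be > 0")
        _per_feature(self.baseline, n, "baseline")
        _per_site(self.site_location_mean, self.n_sites, "site_location_mean")
        if np.any(_per_site(self.site_location_var, self.n_sites, "site_location_var") < 0):
            raise ConfigError("site_location_var must be >= 0")
        if self.site_scale_shape is not None:
            shape = _per_site(self.site_scale_shape, self.n_sites, "site_scale_shape")
            if np.any(shape <= 2):
                raise ConfigError("inverse-gamma shape must be > 2 (finite variance)")
            if np.any(_per_site(self.site_scale_rate, self.n_sites, "site_scale_rate") <= 0):
                raise ConfigError("inverse-gamma rate must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        if not 0 <= self.sex_ratio <= 1:
            raise ConfigError("sex_ratio must be in [0, 1]")
        if self.age_range[1] < self.age_range[0]:
            raise ConfigError("age_range must be (low, high) with low <= high")

    @property
    def site_names(self) -> list[str]:
        return [f"site{i + 1:02d}" for i in range(self.n_sites)]


@dataclass(frozen=True)
class GroundTruth:
    """Realized site effects and the planted group signal."""

    site_names: tuple[str, ...]
    feature_names: tuple[str, ...]
    gamma: np.ndarray  # n_sites x N additive shifts
    delta: np.ndarray  # n_sites x N multiplicative scales
    affected_features: tuple[str, ...]
    effect_size: float

    def __post_init__(self) -> None:
        expected = (len(self.site_names), len(self.feature_names))
        if self.gamma.shape != expected or self.delta.shape != expected:
            raise ConfigError(f"gamma/delta must have shape {expected}")


def generate_cohort(config: GeneratorConfig) -> tuple[ROICohort, GroundTruth]:
    """Draw one cohort + its ground truth, fully determined by ``config.seed``."""
    schema = config.schema
    n_feat = len(schema)
    n_sites = config.n_sites
    rng = np.random.default_rng(config.seed)

    alpha = _per_feature(config.baseline, n_feat, "baseline")
    sigma = _per_feature(config.noise_sd, n_feat, "noise_sd")
    gamma_bar = _per_site(config.site_location_mean, n_sites, "site_location_mean")
    tau2 = _per_site(config.site_location_var, n_sites, "site_location_var")

    gamma = gamma_bar[:, None] + np.sqrt(tau2)[:, None] * rng.standard_normal((n_sites, n_feat))
    if config.site_scale_shape is None:
        delta = np.ones((n_sites, n_feat))
    else:
        shape = _per_site(config.site_scale_shape, n_sites, "site_scale_shape")
        rate = _per_site(config.site_scale_rate, n_sites, "site_scale_rate")
        # delta^2 ~ InvGamma(shape, rate): reciprocal of a Gamma(shape, scale=1/rate) draw
        delta = np.sqrt(1.0 / rng.gamma(shape[:, None], 1.0 / rate[:, None], (n_sites, n_feat)))

    affected_names = schema.subset_names(config.affected_rois)
    affected_mask = np.isin(schema.names, affected_names)

    rows: list[dict] = []
    blocks: list[np.ndarray] = []
    lo, hi = config.age_range
    for i, site in enumerate(config.site_names):
        for group, count in config.n_per_site.items():
            is_case = group != "HC"
            age = rng.uniform(lo, hi, count)
            sex = (rng.random(count) < config.sex_ratio).astype(int)
            eps = rng.standard_normal((count, n_feat)) * sigma
            y = (
                alpha
                + config.beta_age * age[:, None] / 10.0
                + config.beta_sex * sex[:, None]
                + gamma[i]
                + delta[i] * eps
            )
            if is_case and config.effect_size > 0:
                y += config.effect_size * sigma * affected_mask
            blocks.append(y)
            for k in range(count):
                rows.append(
                    {
                        "subject_id": f"{site}_{group}_{k:04d}",
                        "group": group,
                        "site": site,
                        "age": age[k],
                        "sex": int(sex[k]),
                    }
                )

    X = np.vstack(blocks)
    if config.missing_rate > 0:
        mask = rng.random(X.shape) < config.missing_rate
        X = X.copy()
        X[mask] = np.nan

    subjects = pd.DataFrame(rows, columns=list(META_COLUMNS))
    cohort = ROICohort(subjects=subjects, X=X, schema=schema)
    truth = GroundTruth(
        site_names=tuple(config.site_names),
        feature_names=tuple(schema.names),
        gamma=gamma,
        delta=delta,
        affected_features=tuple(affected_names),
        effect_size=config.effect_size if affected_names else 0.0,
    )
    return cohort, truth


def describe_truth(truth: GroundTruth) -> pd.DataFrame:
    """Long-format summary: one row per (site, feature) with shift, scale,
    affected flag and the planted effect size."""
    records = []
    affected = set(truth.affected_features)
    for i, site in enumerate(truth.site_names):
        for g, name in enumerate(truth.feature_names):
            records.append(
                {
                    "site": site,
                    "feature": name,
                    "gamma": truth.gamma[i, g],
                    "delta": truth.delta[i, g],
                    "affected": name in affected,
                    "effect_size": truth.effect_size,
                }
            )
    return pd.DataFrame.from_records(records)


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    describe_truth(truth).to_csv(path, index=False)
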