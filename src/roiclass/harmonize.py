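"""Empirical-Bayes location/scale harmonization across acquisition sites.

Implements the parametric ComBat procedure: per-feature least-squares
standardization over a design of site indicators plus covariates, site-wise
location/scale estimates shrunk to empirical-Bayes posteriors under a
normal / inverse-gamma prior, and reconstruction with the site terms removed.

By default the covariate design includes age (centered) and sex, and the
covariate terms are NOT added back at reconstruction, so site, age and sex
differences are all minimized. Pass ``restore=("age", "sex")`` for the
classic behavior that preserves covariate effects. The group label can be
protected by adding ``"group"`` to the design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import ROICohort

_VALID_COVARIATES = ("age", "sex", "group")


class HarmonizationError(ValueError):
    """Raised for cohorts that cannot be harmonized."""


@dataclass
class HarmonizationModel:
    """Fitted standardization plus per-site empirical-Bayes adjustments."""

    feature_names: tuple[str, ...]
    sites: tuple[str, ...]
    n_per_site: tuple[int, ...]
    covariates: tuple[str, ...]
    age_mean: float
    alpha: np.ndarray  # per-feature grand intercept
    beta: dict  # covariate name -> per-feature coefficient vector
    sigma: np.ndarray  # per-feature pooled SD
    gamma_star: np.ndarray  # n_sites x N EB location
    delta_star: np.ndarray  # n_sites x N EB scale (>0)
    gamma_hat: np.ndarray  # n_sites x N raw location
    delta_hat: np.ndarray  # n_sites x N raw scale
    prior_location_mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    prior_location_var: np.ndarray = field(default_factory=lambda: np.zeros(0))
    prior_scale_shape: np.ndarray = field(default_factory=lambda: np.zeros(0))
    prior_scale_rate: np.ndarray = field(default_factory=lambda: np.zeros(0))
    n_iterations: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if np.any(self.delta_star <= 0):
            raise HarmonizationError("posterior scale factors must be positive")
        if self.gamma_star.shape[0] != len(self.sites):
            raise HarmonizationError("one site block required per fitted site")

    def site_index(self, site: str) -> int:
        try:
            return self.sites.index(site)
        except ValueError:
            raise HarmonizationError(f"site {site!r} was not seen at fit time") from None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "sites": list(self.sites),
            "n_per_site": list(self.n_per_site),
            "covariates": list(self.covariates),
            "age_mean": self.age_mean,
            "alpha": self.alpha.tolist(),
            "beta": {k: v.tolist() for k, v in self.beta.items()},
            "sigma": self.sigma.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "gamma_hat": self.gamma_hat.tolist(),
            "delta_hat": self.delta_hat.tolist(),
            "prior_location_mean": self.prior_location_mean.tolist(),
            "prior_location_var": self.prior_location_var.tolist(),
            "prior_scale_shape": self.prior_scale_shape.tolist(),
            "prior_scale_rate": self.prior_scale_rate.tolist(),
            "n_iterations": list(self.n_iterations),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "HarmonizationModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            feature_names=tuple(payload["feature_names"]),
            sites=tuple(payload["sites"]),
            n_per_site=tuple(payload["n_per_site"]),
            covariates=tuple(payload["covariates"]),
            age_mean=payload["age_mean"],
            alpha=np.asarray(payload["alpha"]),
            beta={k: np.asarray(v) for k, v in payload["beta"].items()},
            sigma=np.asarray(payload["sigma"]),
            gamma_star=np.asarray(payload["gamma_star"]),
            delta_star=np.asarray(payload["delta_star"]),
            gamma_hat=np.asarray(payload["gamma_hat"]),
            delta_hat=np.asarray(payload["delta_hat"]),
            prior_location_mean=np.asarray(payload["prior_location_mean"]),
            prior_location_var=np.asarray(payload["prior_location_var"]),
            prior_scale_shape=np.asarray(payload["prior_scale_shape"]),
            prior_scale_rate=np.asarray(payload["prior_scale_rate"]),
            n_iterations=tuple(payload["n_iterations"]),
        )


def _covariate_matrix(cohort: ROICohort, covariates: Sequence[str], age_mean: float) -> np.ndarray:
    cols = []
    for cov in covariates:
        if cov == "age":
            cols.append(cohort.subjects["age"].to_numpy(dtype=float) - age_mean)
        elif cov == "sex":
            cols.append(cohort.subjects["sex"].to_numpy(dtype=float))
        elif cov == "group":
            cols.append((cohort.groups != "HC").astype(float))
    if not cols:
        return np.zeros((cohort.n_subjects, 0))
    return np.column_stack(cols)


def _eb_site_posterior(
    z_site: np.ndarray,
    gamma_hat: np.ndarray,
    delta2_hat: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, float, float, float, int]:
    """Iterate the normal / inverse-gamma posterior equations for one site.

    Returns (gamma_star, delta_star, prior mean, prior var, prior shape,
    prior rate, iterations).
    """
    n = z_site.shape[0]
    g_bar = float(np.mean(gamma_hat))
    t2 = float(np.var(gamma_hat, ddof=1)) if gamma_hat.size > 1 else 0.0
    m = float(np.mean(delta2_hat))
    s2 = float(np.var(delta2_hat, ddof=1)) if delta2_hat.size > 1 else 0.0

    if s2 <= 1e-12:
        # degenerate scale prior (identical delta_hat across features): no shrinkage
        lam = float("inf")
        theta = float("inf")
        if t2 <= 1e-12:
            return gamma_hat.copy(), np.sqrt(delta2_hat), g_bar, t2, lam, theta, 0
        gamma_star = gamma_hat.copy()
        delta2_star = delta2_hat.copy()
        for it in range(1, max_iter + 1):
            g_new = (n * t2 * gamma_hat + delta2_star * g_bar) / (n * t2 + delta2_star)
            change = float(np.max(np.abs(g_new - gamma_star)))
            gamma_star = g_new
            if change < tol:
                break
        return gamma_star, np.sqrt(delta2_star), g_bar, t2, lam, theta, it

    lam = (2.0 * s2 + m**2) / s2  # method-of-moments inverse-gamma shape
    theta = (m * s2 + m**3) / s2  # and rate

    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    it = 0
    for it in range(1, max_iter + 1):
        g_new = (n * t2 * gamma_hat + delta2_star * g_bar) / (n * t2 + delta2_star)
        ssq = np.sum((z_site - g_new[None, :]) ** 2, axis=0)
        d_new = (theta + 0.5 * ssq) / (n / 2.0 + lam - 1.0)
        change = max(
            float(np.max(np.abs(g_new - gamma_star))),
            float(np.max(np.abs(d_new - delta2_star))),
        )
        gamma_star, delta2_star = g_new, d_new
        if change < tol:
            break
    return gamma_star, np.sqrt(delta2_star), g_bar, t2, lam, theta, it


def fit_combat(
    cohort: ROICohort,
    covariates: Sequence[str] = ("age", "sex"),
    tol: float = 1e-4,
    max_iter: int = 100,
) -> HarmonizationModel:
    """Fit the harmonization model on a complete-case cohort.

    Requires at least two subjects per site and non-degenerate features;
    a zero-variance feature is reported by name.
    """
    for cov in covariates:
        if cov not in _VALID_COVARIATES:
            raise HarmonizationError(f"unknown covariate {cov!r}")
    Y = np.asarray(cohort.X, dtype=float)
    if np.isnan(Y).any():
        raise HarmonizationError("cohort contains missing values; filter complete cases first")
    zero_var = np.flatnonzero(np.ptp(Y, axis=0) == 0)
    if zero_var.size:
        name = cohort.schema.names[int(zero_var[0])]
        raise HarmonizationError(f"feature {name!r} has zero variance")

    site_labels = cohort.sites
    sites = tuple(dict.fromkeys(site_labels))  # first-appearance order
    site_idx = [np.flatnonzero(site_labels == s) for s in sites]
    n_per_site = tuple(len(ix) for ix in site_idx)
    for s, n in zip(sites, n_per_site):
        if n < 2:
            raise HarmonizationError(f"site {s!r} has fewer than 2 subjects")

    n_total, n_feat = Y.shape
    age_mean = float(cohort.subjects["age"].mean())
    C = _covariate_matrix(cohort, covariates, age_mean)
    onehot = np.zeros((n_total, len(sites)))
    for i, ix in enumerate(site_idx):
        onehot[ix, i] = 1.0
    design = np.hstack([onehot, C])

    B, *_ = np.linalg.lstsq(design, Y, rcond=None)
    site_coef = B[: len(sites)]  # per-site intercepts
    cov_coef = B[len(sites):]
    weights = np.asarray(n_per_site, dtype=float) / n_total
    alpha = weights @ site_coef  # sample-size weighted grand intercept

    fitted = design @ B
    sigma2 = np.mean((Y - fitted) ** 2, axis=0)  # pooled, divisor n
    sigma = np.sqrt(sigma2)

    Z = (Y - alpha[None, :] - C @ cov_coef) / sigma[None, :]

    gamma_hat = np.vstack([Z[ix].mean(axis=0) for ix in site_idx])
    # divisor-n site variance keeps single-site harmonization an exact identity
    delta2_hat = np.vstack([Z[ix].var(axis=0, ddof=0) for ix in site_idx])

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta2_hat)
    pr_mean, pr_var, pr_shape, pr_rate, iters = [], [], [], [], []
    for i, ix in enumerate(site_idx):
        g, d, gm, gv, lam, theta, it = _eb_site_posterior(
            Z[ix], gamma_hat[i], delta2_hat[i], tol, max_iter
        )
        gamma_star[i] = g
        delta_star[i] = d
        pr_mean.append(gm)
        pr_var.append(gv)
        pr_shape.append(lam)
        pr_rate.append(theta)
        iters.append(it)

    beta = {cov: cov_coef[k] for k, cov in enumerate(covariates)}
    return HarmonizationModel(
        feature_names=tuple(cohort.schema.names),
        sites=sites,
        n_per_site=n_per_site,
        covariates=tuple(covariates),
        age_mean=age_mean,
        alpha=alpha,
        beta=beta,
        sigma=sigma,
        gamma_star=gamma_star,
        delta_star=delta_star,
        gamma_hat=gamma_hat,
        delta_hat=np.sqrt(delta2_hat),
        prior_location_mean=np.asarray(pr_mean),
        prior_location_var=np.asarray(pr_var),
        prior_scale_shape=np.asarray(pr_shape),
        prior_scale_rate=np.asarray(pr_rate),
        n_iterations=tuple(iters),
    )


def apply_combat(
    model: HarmonizationModel,
    cohort: ROICohort,
    restore: Sequence[str] = (),
) -> ROICohort:
    """Remove fitted site effects; optionally add back covariate terms.

    ``restore=()`` (default) removes site, age and sex effects together;
    ``restore=("age", "sex")`` reconstructs the covariate contributions.
    """
    if tuple(cohort.schema.names) != model.feature_names:
        raise HarmonizationError("cohort schema does not match the fitted model")
    for cov in restore:
        if cov not in model.covariates:
            raise HarmonizationError(f"cannot restore {cov!r}: not in the fitted design")
    Y = np.asarray(cohort.X, dtype=float)
    C = _covariate_matrix(cohort, model.covariates, model.age_mean)
    cov_term = sum(
        (C[:, [k]] @ model.beta[cov][None, :] for k, cov in enumerate(model.covariates)),
        np.zeros_like(Y),
    )
    Z = (Y - model.alpha[None, :] - cov_term) / model.sigma[None, :]

    out = np.empty_like(Y)
    site_labels = cohort.sites
    for site in np.unique(site_labels):
        i = model.site_index(site)
        ix = np.flatnonzero(site_labels == site)
        out[ix] = (Z[ix] - model.gamma_star[i]) / model.delta_star[i]

    out = out * model.sigma[None, :] + model.alpha[None, :]
    if restore:
        restore_term = sum(
            C[:, [model.covariates.index(cov)]] @ model.beta[cov][None, :] for cov in restore
        )
        out = out + restore_term
    return cohort.with_matrix(out)


def harmonize_cohort(
    cohort: ROICohort,
    covariates: Sequence[str] = ("age", "sex"),
    restore: Sequence[str] = (),
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[ROICohort, HarmonizationModel]:
    """Convenience fit + apply on the same cohort."""
    model = fit_combat(cohort, covariates=covariates, tol=tol, max_iter=max_iter)
    return apply_combat(model, cohort, restore=restore), model
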