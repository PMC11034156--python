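"""Parametric empirical-Bayes ComBat for multi-site feature tables.

The location/scale model assumes each feature f measured at site s on
participant i decomposes as

    Y_isf = alpha_f + X_i beta_f + gamma_sf + delta_sf * eps_isf,

with eps ~ N(0, sigma_f^2).  Fitting proceeds in three stages:

1. **Standardization** — per-feature least squares of Y on covariates and
   site indicators under the identifiability constraint
   ``sum_s n_s gamma_hat_sf = 0``, pooled variance ``sigma_hat_f^2``
   computed with the 1/N divisor, and standardized data
   ``Z = (Y - alpha_hat - X beta_hat) / sigma_hat``.
2. **Empirical-Bayes shrinkage** — per site, the per-feature standardized
   site means and variances are shrunk toward cross-feature priors
   (normal for the shift, inverse-gamma for the squared scale) whose
   hyperparameters come from method of moments; the conditional-posterior
   updates are iterated to convergence.
3. **Adjustment** — ``Y_hat = sigma_hat * (Z - gamma_star)/delta_star
   + alpha_hat + X beta_hat``, which removes the estimated site effects
   while restoring all covariate-explained structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FeatureTable

DEFAULT_COVARIATES = ["age", "sex", "diagnosis", "race", "education", "apoe2", "apoe4"]

CONTINUOUS = {"age", "education"}


class ConvergenceError(RuntimeError):
    """EM updates failed to converge; carries the last max change."""

    def __init__(self, last_change: float, max_iter: int):
        self.last_change = last_change
        self.max_iter = max_iter
        super().__init__(
            f"EB updates did not converge in {max_iter} iterations "
            f"(last max change {last_change:.3e})"
        )


def build_design(table: FeatureTable, covariate_names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Covariate design matrix (no intercept, no site columns).

    Continuous covariates enter untransformed; binaries as 0/1; the
    categorical ``race`` is one-hot coded with its first level as
    reference.  Returns the matrix and its column names.
    """
    cov = table.covariates
    cols: list[np.ndarray] = []
    names: list[str] = []
    dropped: list[str] = []
    for name in covariate_names:
        if name not in cov.columns:
            raise ValueError(f"covariate {name!r} not in table")
        series = cov[name]
        if series.dtype == object or str(series.dtype) == "category":
            levels = sorted(pd.unique(series.astype(str)))
            for lvl in levels[1:]:
                cols.append((series.astype(str) == lvl).to_numpy(float))
                names.append(f"{name}[{lvl}]")
        else:
            col = series.to_numpy(float)
            if np.ptp(col) == 0:
                # constant in this (sub)sample: no variation to preserve,
                # and collinear with the site indicators
                dropped.append(name)
                continue
            cols.append(col)
            names.append(name)
    if dropped:
        warnings.warn(
            f"constant covariate(s) dropped from ComBat design: {dropped}",
            UserWarning,
            stacklevel=3,
        )
    if not cols:
        return np.empty((len(cov), 0)), []
    return np.column_stack(cols), names


@dataclass
class CombatFit:
    """All fitted ComBat quantities for one harmonization run."""

    sites: list
    n_per_site: dict
    covariate_names: list[str]
    design_columns: list[str]
    feature_names: list[str]
    alpha_hat: np.ndarray            # (F,)
    beta_hat: np.ndarray             # (F, p) in design_columns order
    sigma_hat: np.ndarray            # (F,)
    gamma_hat: pd.DataFrame          # sites x features, feature units
    Z: np.ndarray                    # (n, F) standardized data
    stand_mean: np.ndarray           # (n, F) alpha_hat + X beta_hat
    gamma_star: pd.DataFrame | None = None  # sites x features, Z units
    delta_star: pd.DataFrame | None = None  # sites x features, > 0
    n_iter: dict = field(default_factory=dict)  # per-site EM iterations
    mode: str = "eb"
    Y_hat: np.ndarray | None = None

    def site_params_frame(self) -> pd.DataFrame:
        """Long (site, feature) frame of gamma_star/delta_star for export."""
        if self.gamma_star is None:
            raise ValueError("EB stage has not run")
        out = (
            pd.concat(
                {"gamma_star": self.gamma_star.stack(),
                 "delta_star": self.delta_star.stack()},
                axis=1,
            )
            .rename_axis(["site", "feature"])
            .reset_index()
        )
        return out

    def feature_params_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"feature": self.feature_names})
        out["alpha_hat"] = self.alpha_hat
        out["sigma_hat"] = self.sigma_hat
        for j, c in enumerate(self.design_columns):
            out[f"beta_{c}"] = self.beta_hat[:, j]
        return out


def fit_standardization(table: FeatureTable, covariate_names: list[str]) -> CombatFit:
    """Constrained least-squares standardization (stages of Eqs. 2-4).

    Solves, per feature, Y ~ covariates + site one-hot (no intercept) and
    re-centers the site coefficients by their sample-size-weighted mean so
    the weighted site effects sum to zero; the weighted mean becomes the
    intercept ``alpha_hat``.
    """
    sites = table.sites
    if len(sites) < 2:
        raise ValueError("ComBat needs at least 2 sites")
    n_per_site = table.n_per_site()
    n_total = table.n_participants
    Y = table.values

    X_cov, design_columns = build_design(table, covariate_names)
    site_onehot = np.column_stack(
        [table.site_mask(s).astype(float) for s in sites]
    )
    design = np.hstack([site_onehot, X_cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {design.shape[1]}); "
            "check for collinear or constant covariates"
        )
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    site_coef = coef[: len(sites), :]              # (S, F)
    beta = coef[len(sites):, :].T                  # (F, p)

    weights = np.array([n_per_site[s] / n_total for s in sites])
    alpha = weights @ site_coef                    # (F,)
    gamma_hat = site_coef - alpha[None, :]         # (S, F), satisfies Eq. 4

    stand_mean = alpha[None, :] + X_cov @ beta.T   # (n, F)
    fitted_full = stand_mean + site_onehot @ gamma_hat
    resid = Y - fitted_full
    sigma2 = np.mean(resid**2, axis=0)             # 1/N divisor, as printed
    scale = np.maximum(1.0, np.abs(Y).max(axis=0))
    degenerate = sigma2 <= (1e-10 * scale) ** 2
    if degenerate.any():
        bad = [table.feature_names[j] for j in np.flatnonzero(degenerate)]
        raise ValueError(f"constant feature(s) with zero residual variance: {bad}")
    sigma = np.sqrt(sigma2)
    Z = (Y - stand_mean) / sigma[None, :]

    return CombatFit(
        sites=sites,
        n_per_site=n_per_site,
        covariate_names=list(covariate_names),
        design_columns=design_columns,
        feature_names=list(table.feature_names),
        alpha_hat=alpha,
        beta_hat=beta,
        sigma_hat=sigma,
        gamma_hat=pd.DataFrame(gamma_hat, index=sites, columns=table.feature_names),
        Z=Z,
        stand_mean=stand_mean,
    )


def _moments_invgamma(mean: float, var: float) -> tuple[float, float]:
    """Method-of-moments inverse-gamma (shape, rate) from mean and variance."""
    shape = mean**2 / var + 2.0
    rate = mean * (shape - 1.0)
    return shape, rate


def eb_estimate(fit: CombatFit, table: FeatureTable, conv: float = 1e-4,
                max_iter: int = 100) -> CombatFit:
    """Empirical-Bayes shrinkage of per-site shift/scale estimates.

    Per site the raw estimates are the per-feature mean (``gamma``) and
    variance (``delta^2``, unbiased divisor) of the standardized data.
    Hyperpriors pool across features by method of moments; the standard
    conditional-posterior updates are iterated until the largest absolute
    change in (gamma_star, delta_star^2) drops below ``conv``.
    """
    F = len(fit.feature_names)
    if F < 2:
        raise ValueError("EB priors pool across features; need >= 2 features")
    gamma_star = {}
    delta_star = {}
    for s in fit.sites:
        mask = table.site_mask(s)
        Zs = fit.Z[mask]
        ns = Zs.shape[0]
        g_hat = Zs.mean(axis=0)                   # (F,)
        d_hat2 = Zs.var(axis=0, ddof=1)           # (F,)
        g_bar = float(np.mean(g_hat))
        t2 = float(np.var(g_hat, ddof=1))
        a_prior, b_prior = _moments_invgamma(
            float(np.mean(d_hat2)), float(np.var(d_hat2, ddof=1))
        )

        g_old = g_hat.copy()
        d_old2 = d_hat2.copy()
        change = np.inf
        it = 0
        while it < max_iter:
            it += 1
            g_new = (t2 * ns * g_hat + d_old2 * g_bar) / (t2 * ns + d_old2)
            sum2 = ((Zs - g_new[None, :]) ** 2).sum(axis=0)
            d_new2 = (0.5 * sum2 + b_prior) / (ns / 2.0 + a_prior - 1.0)
            change = max(
                float(np.max(np.abs(g_new - g_old))),
                float(np.max(np.abs(d_new2 - d_old2))),
            )
            g_old, d_old2 = g_new, d_new2
            if change < conv:
                break
        else:
            raise ConvergenceError(change, max_iter)
        gamma_star[s] = g_old
        delta_star[s] = np.sqrt(d_old2)
        fit.n_iter[s] = it

    fit.gamma_star = pd.DataFrame(gamma_star, index=fit.feature_names).T
    fit.delta_star = pd.DataFrame(delta_star, index=fit.feature_names).T
    fit.mode = "eb"
    return fit


def moments_estimate(fit: CombatFit, table: FeatureTable) -> CombatFit:
    """No-shrinkage variant: per-site sample moments of Z used directly.

    Gives exact per-site location/scale matching after adjustment, which
    the EB shrinkage only approximates.
    """
    gamma_star = {}
    delta_star = {}
    for s in fit.sites:
        Zs = fit.Z[table.site_mask(s)]
        gamma_star[s] = Zs.mean(axis=0)
        delta_star[s] = np.sqrt(Zs.var(axis=0, ddof=1))
        fit.n_iter[s] = 0
    fit.gamma_star = pd.DataFrame(gamma_star, index=fit.feature_names).T
    fit.delta_star = pd.DataFrame(delta_star, index=fit.feature_names).T
    fit.mode = "no_eb"
    return fit


def adjust(fit: CombatFit, table: FeatureTable) -> FeatureTable:
    """Remove the estimated site effects (Eq.-5 adjustment)."""
    if fit.gamma_star is None or fit.delta_star is None:
        raise ValueError("fit has no site-effect estimates; run the EB stage first")
    if (fit.delta_star.to_numpy() <= 0).any():
        raise ValueError("delta_star must be positive everywhere")
    sites = table.covariates["site"].to_numpy()
    gamma = fit.gamma_star.loc[sites].to_numpy()
    delta = fit.delta_star.loc[sites].to_numpy()
    Y_hat = fit.sigma_hat[None, :] * (fit.Z - gamma) / delta + fit.stand_mean
    fit.Y_hat = Y_hat
    return FeatureTable(
        covariates=table.covariates.copy(),
        values=Y_hat,
        feature_names=list(table.feature_names),
    )


def harmonize(table: FeatureTable, covariate_names: list[str] | None = None,
              mode: str = "eb", conv: float = 1e-4,
              max_iter: int = 100) -> tuple[FeatureTable, CombatFit]:
    """Full pipeline: standardize, estimate site effects, adjust.

    ``mode='eb'`` applies empirical-Bayes shrinkage; ``mode='no_eb'``
    uses raw per-site moments (exact location/scale matching).
    """
    if covariate_names is None:
        covariate_names = list(DEFAULT_COVARIATES)
    if mode not in ("eb", "no_eb"):
        raise ValueError(f"unknown mode {mode!r}; expected 'eb' or 'no_eb'")
    fit = fit_standardization(table, covariate_names)
    if mode == "eb":
        fit = eb_estimate(fit, table, conv=conv, max_iter=max_iter)
    else:
        fit = moments_estimate(fit, table)
    harmonized = adjust(fit, table)
    return harmonized, fit
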