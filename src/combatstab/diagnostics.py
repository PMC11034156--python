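"""Model-assumption diagnostics for ComBat fits.

Parametric ComBat assumes (1) normal model residuals, (2) normal
additive site effects gamma_star and inverse-gamma squared scales
delta_star^2 across features, and (3) uncorrelated covariates.  This
module quantifies adherence: average negative log-likelihoods under
moment-fitted normal / inverse-gamma distributions, Anderson-Darling
normality tests with the small-sample correction for estimated
parameters, and a Pearson correlation matrix over coded covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .combat import CombatFit
from .data import FeatureTable

#: Stephens' case-4 critical values (mean and variance estimated)
AD_SIGNIFICANCE = np.array([0.15, 0.10, 0.05, 0.025, 0.01])
AD_CRITICAL = np.array([0.576, 0.656, 0.787, 0.918, 1.092])


@dataclass
class InvGammaFit:
    """Moment-matched inverse-gamma parameters of a positive sample."""

    mu_ig: float
    sigma2_ig: float
    alpha_tilde: float  # shape
    beta_tilde: float   # rate


@dataclass
class DiagnosticsReport:
    """Assumption-adherence summary for one ComBat run."""

    nll_residuals_f: pd.Series          # per feature
    nll_gamma_s: dict                   # site -> avg NLL (NaN if degenerate)
    nll_delta_s: dict                   # site -> avg NLL
    invgamma_fits: dict                 # site -> InvGammaFit | None
    ad_statistic_f: pd.Series
    ad_reject_f: pd.Series
    covariate_correlations: pd.DataFrame
    delta_on: str = "squared"           # diagnostic applied to delta*^2 or delta*
    vs_silver: dict = field(default_factory=dict)  # metric -> difference

    @property
    def mean_nll_residuals(self) -> float:
        return float(self.nll_residuals_f.mean())

    @property
    def ad_rejection_rate(self) -> float:
        return float(self.ad_reject_f.mean())


def fit_invgamma_moments(values: np.ndarray, ddof: int = 1) -> InvGammaFit:
    """Shape/rate by moment inversion: alpha = mu^2/var + 2, beta = mu(alpha-1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if np.any(x <= 0):
        raise ValueError("inverse-gamma diagnostics need strictly positive values")
    mu = float(np.mean(x))
    var = float(np.var(x, ddof=ddof))
    if var == 0:
        raise ValueError("zero variance; inverse-gamma moments undefined")
    alpha = mu**2 / var + 2.0
    beta = mu * (alpha - 1.0)
    return InvGammaFit(mu_ig=mu, sigma2_ig=var, alpha_tilde=alpha, beta_tilde=beta)


def invgamma_moments(alpha: float, beta: float) -> tuple[float, float]:
    """Closed-form (mean, variance) of InvGamma(shape=alpha, rate=beta)."""
    if alpha <= 2:
        raise ValueError("variance finite only for shape > 2")
    mean = beta / (alpha - 1.0)
    var = beta**2 / ((alpha - 1.0) ** 2 * (alpha - 2.0))
    return mean, var


def avg_nll_normal(values: np.ndarray) -> float:
    """Average negative log-likelihood under a moment-fitted normal.

    The fit uses the sample mean and the maximum-likelihood (1/n)
    standard deviation.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mu = np.mean(x)
    var = np.var(x)  # ML, 1/n
    if var == 0:
        raise ValueError("zero spread; normal NLL undefined")
    return float(0.5 * np.log(2 * np.pi * var) + np.mean((x - mu) ** 2) / (2 * var))


def avg_nll_invgamma(values: np.ndarray, fit: InvGammaFit | None = None) -> float:
    """Average NLL under the moment-fitted inverse gamma, in log space."""
    x = np.asarray(values, dtype=float)
    if fit is None:
        fit = fit_invgamma_moments(x)
    if np.any(x <= 0):
        raise ValueError("inverse-gamma support is (0, inf)")
    a, b = fit.alpha_tilde, fit.beta_tilde
    logpdf = a * np.log(b) - gammaln(a) - (a + 1.0) * np.log(x) - b / x
    return float(-np.mean(logpdf))


def anderson_darling_normal(values: np.ndarray, level: float = 0.05) -> tuple[float, bool]:
    """A^2 test of normality with estimated mean and variance.

    Returns the corrected statistic ``A^2 (1 + 4/n - 25/n^2)`` and the
    rejection decision at ``level`` (one of 0.15, 0.10, 0.05, 0.025, 0.01).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 8:
        raise ValueError("Anderson-Darling needs at least 8 values")
    matches = np.isclose(AD_SIGNIFICANCE, level)
    if not matches.any():
        raise ValueError(f"level must be one of {AD_SIGNIFICANCE.tolist()}")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("zero spread; normality test undefined")
    w = (x - np.mean(x)) / sd
    from scipy.stats import norm

    logcdf = norm.logcdf(w)
    logsf = norm.logsf(w)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (logcdf + logsf[::-1]))
    a2_corr = a2 * (1.0 + 4.0 / n - 25.0 / n**2)
    crit = AD_CRITICAL[matches.argmax()]
    return float(a2_corr), bool(a2_corr > crit)


def covariate_correlation(table: FeatureTable) -> pd.DataFrame:
    """Pearson correlations over numerically coded covariates.

    Binaries enter as 0/1, race as a reference-coded indicator, site as
    the site-2 indicator.  Constant covariates yield NaN rows/columns
    (reported undefined, not dropped).
    """
    cov = table.covariates
    sites = table.sites
    coded = pd.DataFrame({
        "age": cov["age"].astype(float),
        "sex": cov["sex"].astype(float),
        "diagnosis": cov["diagnosis"].astype(float),
        "race_other": (cov["race"] != "nonhispanic_white").astype(float),
        "education": cov["education"].astype(float),
        "apoe2": cov["apoe2"].astype(float),
        "apoe4": cov["apoe4"].astype(float),
        "site": (cov["site"] == sites[-1]).astype(float),
    })
    if coded.shape[1] < 2:
        raise ValueError("need at least 2 covariates")
    corr = coded.corr(method="pearson")
    constant = coded.std(ddof=0) == 0
    for name in coded.columns[constant]:
        corr.loc[name, :] = np.nan
        corr.loc[:, name] = np.nan
    for name in coded.columns[~constant]:
        corr.loc[name, name] = 1.0
    return corr


def model_residuals(fit: CombatFit, table: FeatureTable) -> np.ndarray:
    """Standardization-model residuals Y - alpha - X beta - gamma_hat."""
    sites = table.covariates["site"].to_numpy()
    gamma = fit.gamma_hat.loc[sites].to_numpy()
    return fit.sigma_hat[None, :] * fit.Z - gamma


def diagnose_run(fit: CombatFit, table: FeatureTable,
                 silver_diag: DiagnosticsReport | None = None,
                 level: float = 0.05, delta_on: str = "squared") -> DiagnosticsReport:
    """Full assumption check for one harmonization run.

    ``delta_on='squared'`` applies the inverse-gamma diagnostic to
    delta_star^2 (the quantity the EB prior governs); ``'raw'`` applies
    it to delta_star itself.
    """
    if fit.gamma_star is None:
        raise ValueError("fit has no EB estimates")
    if delta_on not in ("squared", "raw"):
        raise ValueError("delta_on must be 'squared' or 'raw'")
    resid = model_residuals(fit, table)
    nll_res, ad_stat, ad_rej = [], [], []
    for j in range(resid.shape[1]):
        col = resid[:, j]
        try:
            nll_res.append(avg_nll_normal(col))
        except ValueError:
            nll_res.append(np.nan)
        try:
            s, r = anderson_darling_normal(col, level=level)
        except ValueError:
            s, r = np.nan, False
        ad_stat.append(s)
        ad_rej.append(r)
    idx = pd.Index(fit.feature_names, name="feature")
    nll_res = pd.Series(nll_res, index=idx)
    ad_stat = pd.Series(ad_stat, index=idx)
    ad_rej = pd.Series(ad_rej, index=idx)

    nll_gamma, nll_delta, ig_fits = {}, {}, {}
    for s in fit.sites:
        g = fit.gamma_star.loc[s].to_numpy()
        try:
            nll_gamma[s] = avg_nll_normal(g)
        except ValueError:
            nll_gamma[s] = np.nan
        d = fit.delta_star.loc[s].to_numpy()
        d = d**2 if delta_on == "squared" else d
        try:
            ig = fit_invgamma_moments(d)
            ig_fits[s] = ig
            nll_delta[s] = avg_nll_invgamma(d, ig)
        except ValueError:
            ig_fits[s] = None
            nll_delta[s] = np.nan

    report = DiagnosticsReport(
        nll_residuals_f=nll_res,
        nll_gamma_s=nll_gamma,
        nll_delta_s=nll_delta,
        invgamma_fits=ig_fits,
        ad_statistic_f=ad_stat,
        ad_reject_f=ad_rej,
        covariate_correlations=covariate_correlation(table),
        delta_on=delta_on,
    )
    if silver_diag is not None:
        diffs = {"nll_residuals": report.mean_nll_residuals
                 - silver_diag.mean_nll_residuals}
        for s in fit.sites:
            diffs[f"nll_gamma_{s}"] = report.nll_gamma_s[s] - silver_diag.nll_gamma_s.get(s, np.nan)
            diffs[f"nll_delta_{s}"] = report.nll_delta_s[s] - silver_diag.nll_delta_s.get(s, np.nan)
        report.vs_silver = diffs
    return report
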