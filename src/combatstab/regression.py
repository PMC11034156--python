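"""Post-harmonization association models.

Per feature we fit the age-association regression

    Y ~ 1 + age + sex + site + diagnosis

either by OLS (on harmonized or raw data) or as a linear mixed-effects
model with a random site intercept replacing the fixed site term.  The
age coefficient divided by a reference fit's standard error gives the
standardized (unitless) age effect used throughout the stability
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import FeatureTable

MODEL_KINDS = ("combat_ols", "plain_ols", "lme")

#: fixed-effect covariates of the association model, in design order
BASE_TERMS = ["age", "sex", "site", "diagnosis"]
#: extra terms for the all-covariate variant
EXTRA_TERMS = ["race_other", "education", "apoe2", "apoe4"]


@dataclass
class RegressionFit:
    """Per-feature coefficients and standard errors of one model fit.

    ``params`` is indexed by feature with columns ``beta_age``,
    ``se_beta_age``, ``beta_sex``, ``beta_site`` (NaN for the LME, where
    site is random), ``beta_mci`` and, for the LME, ``b_site`` (the
    random-intercept variance).
    """

    model_kind: str
    params: pd.DataFrame
    dropped_terms: list[str]

    @property
    def beta_age(self) -> pd.Series:
        return self.params["beta_age"]

    @property
    def se_beta_age(self) -> pd.Series:
        return self.params["se_beta_age"]

    def to_frame(self) -> pd.DataFrame:
        out = self.params.copy()
        out.insert(0, "model_kind", self.model_kind)
        return out.rename_axis("feature").reset_index()


def _design(table: FeatureTable, all_covariates: bool) -> tuple[np.ndarray, list[str], list[str]]:
    """Design matrix with intercept; returns (X, kept terms, dropped terms)."""
    cov = table.covariates
    sites = table.sites
    cols = {"age": cov["age"].to_numpy(float),
            "sex": cov["sex"].to_numpy(float),
            "diagnosis": cov["diagnosis"].to_numpy(float)}
    if len(sites) > 1:
        cols["site"] = (cov["site"] == sites[1]).to_numpy(float)
    else:
        cols["site"] = np.zeros(len(cov))
    if all_covariates:
        cols["race_other"] = (cov["race"] != "nonhispanic_white").to_numpy(float)
        cols["education"] = cov["education"].to_numpy(float)
        cols["apoe2"] = cov["apoe2"].to_numpy(float)
        cols["apoe4"] = cov["apoe4"].to_numpy(float)
    order = BASE_TERMS + (EXTRA_TERMS if all_covariates else [])
    kept, dropped = [], []
    for t in order:
        if np.ptp(cols[t]) == 0:
            dropped.append(t)
        else:
            kept.append(t)
    if dropped:
        warnings.warn(
            f"constant covariate term(s) dropped from OLS design: {dropped}",
            UserWarning,
            stacklevel=3,
        )
    X = np.column_stack([np.ones(len(cov))] + [cols[t] for t in kept])
    return X, kept, dropped


def _ols_all_features(X: np.ndarray, Y: np.ndarray, terms: list[str]) -> pd.DataFrame:
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than design columns ({p})")
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(XtX)
    if rank < p:
        # name the offending column for the caller
        for j in range(1, p):
            sub = X[:, [c for c in range(p) if c != j]]
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(f"rank-deficient design: column {terms[j - 1]!r}")
        raise ValueError("rank-deficient design")
    XtX_inv = np.linalg.inv(XtX)
    coef = XtX_inv @ X.T @ Y                     # (p, F)
    resid = Y - X @ coef
    dof = n - p
    s2 = (resid**2).sum(axis=0) / dof            # (F,)
    se = np.sqrt(np.outer(np.diag(XtX_inv), s2))  # (p, F)
    out = {}
    for j, t in enumerate(terms, start=1):
        out[f"beta_{t}"] = coef[j]
        out[f"se_beta_{t}"] = se[j]
    out["intercept"] = coef[0]
    return pd.DataFrame(out)


def fit_feature_regressions(table: FeatureTable, model_kind: str,
                            all_covariates: bool = False) -> RegressionFit:
    """Fit the age-association model to every feature.

    ``combat_ols`` and ``plain_ols`` are the same OLS (the names record
    whether the input was harmonized); ``lme`` replaces the fixed site
    indicator with a random site intercept (REML, statsmodels MixedLM).
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model_kind {model_kind!r}; expected {MODEL_KINDS}")
    Y = table.values
    if model_kind == "lme":
        return _fit_lme(table, all_covariates)
    X, kept, dropped = _design(table, all_covariates)
    raw = _ols_all_features(X, Y, kept)
    params = pd.DataFrame(index=pd.Index(table.feature_names, name="feature"))
    for t in BASE_TERMS + (EXTRA_TERMS if all_covariates else []):
        col = "beta_mci" if t == "diagnosis" else f"beta_{t}"
        params[col] = raw[f"beta_{t}"].to_numpy() if t in kept else np.nan
    params["se_beta_age"] = raw["se_beta_age"].to_numpy() if "age" in kept else np.nan
    return RegressionFit(model_kind=model_kind, params=params, dropped_terms=dropped)


def _fit_lme(table: FeatureTable, all_covariates: bool) -> RegressionFit:
    import statsmodels.api as sm

    sites = table.sites
    if len(sites) < 2:
        raise ValueError("site has one level; the LME random intercept is undefined")
    cov = table.covariates
    fixed = {"age": cov["age"].to_numpy(float),
             "sex": cov["sex"].to_numpy(float),
             "diagnosis": cov["diagnosis"].to_numpy(float)}
    if all_covariates:
        fixed["race_other"] = (cov["race"] != "nonhispanic_white").to_numpy(float)
        fixed["education"] = cov["education"].to_numpy(float)
        fixed["apoe2"] = cov["apoe2"].to_numpy(float)
        fixed["apoe4"] = cov["apoe4"].to_numpy(float)
    terms = [t for t in fixed if np.ptp(fixed[t]) > 0]
    X = np.column_stack([np.ones(len(cov))] + [fixed[t] for t in terms])
    groups = cov["site"].to_numpy()

    rows = []
    for j, fname in enumerate(table.feature_names):
        y = table.values[:, j]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = sm.MixedLM(y, X, groups=groups)
                res = model.fit(reml=True, method="lbfgs")
                fe = dict(zip(["intercept"] + terms, res.fe_params))
                se = dict(zip(["intercept"] + terms, res.bse_fe))
                row = {
                    "beta_age": fe.get("age", np.nan),
                    "se_beta_age": se.get("age", np.nan),
                    "beta_sex": fe.get("sex", np.nan),
                    "beta_site": np.nan,
                    "beta_mci": fe.get("diagnosis", np.nan),
                    "b_site": float(np.squeeze(res.cov_re)),
                    "converged": bool(res.converged),
                }
            except Exception as exc:  # per-feature failure must not kill the sweep
                row = {k: np.nan for k in
                       ["beta_age", "se_beta_age", "beta_sex", "beta_site",
                        "beta_mci", "b_site"]}
                row["converged"] = False
                row["error"] = str(exc)
        rows.append(row)
    params = pd.DataFrame(rows, index=pd.Index(table.feature_names, name="feature"))
    return RegressionFit(model_kind="lme", params=params, dropped_terms=[])


def normalize_beta(fit: RegressionFit, reference: RegressionFit) -> pd.Series:
    """Standardized age effects: fit's beta_age / reference's se_beta_age."""
    missing = fit.params.index.difference(reference.params.index)
    if len(missing):
        raise ValueError(f"reference fit lacks features: {list(missing)[:5]}")
    ref_se = reference.se_beta_age.reindex(fit.params.index)
    if (ref_se == 0).any() or ref_se.isna().any():
        bad = ref_se.index[(ref_se == 0) | ref_se.isna()][:5]
        raise ValueError(f"reference SE is zero/undefined for features: {list(bad)}")
    return fit.beta_age / ref_se
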