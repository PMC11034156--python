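"""Silver-standard-referenced stability metrics.

Every bootstrap run is scored against the reference ("silver standard")
fit by three error families, each computed per feature as the RMSE
across iterations and then averaged over features:

- standardized age effect: (beta_age - silver beta_age) / silver SE;
- additive site effects gamma_star, per site and as the between-site
  difference, left on their native (standardized-data) scale;
- log multiplicative site effects log(delta_star), per site and as the
  between-site difference (natural log).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .combat import CombatFit
from .grid import RunResult
from .regression import RegressionFit


@dataclass
class StabilityReport:
    """Long-format per-cell metric table.

    Columns: ``point_id, total_n, imbalance, shift, direction, metric,
    site, value, n_runs`` — ``site`` is empty for feature-level and
    between-site-difference metrics.
    """

    long: pd.DataFrame

    def to_csv(self, path) -> None:
        self.long.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StabilityReport":
        df = pd.read_csv(path, float_precision="round_trip")
        df["site"] = df["site"].fillna("").astype(str)
        return cls(df)


def _rmse_then_mean(errors: np.ndarray) -> float:
    """errors shape (iterations, features): per-feature RMSE, then mean."""
    return float(np.mean(np.sqrt(np.mean(errors**2, axis=0))))


def compute_stability(results: list[RunResult],
                      silver: tuple[CombatFit, RegressionFit]) -> StabilityReport:
    """Score every grid cell's runs against the silver-standard fit."""
    silver_fit, silver_reg = silver
    features = list(silver_fit.feature_names)
    s1, s2 = silver_fit.sites
    silver_beta = silver_reg.beta_age.reindex(features).to_numpy()
    silver_se = silver_reg.se_beta_age.reindex(features).to_numpy()
    if np.any(~np.isfinite(silver_se)) or np.any(silver_se == 0):
        raise ValueError("silver-standard SEs must be finite and nonzero")
    silver_gamma = silver_fit.gamma_star.loc[[s1, s2], features].to_numpy()
    silver_logdelta = np.log(silver_fit.delta_star.loc[[s1, s2], features].to_numpy())

    groups: dict[str, list[RunResult]] = {}
    for r in results:
        if r.status != "ok":
            continue
        groups.setdefault(r.run.point.point_id, []).append(r)

    rows = []
    for point_id, runs in groups.items():
        p = runs[0].run.point
        if not runs:
            raise ValueError(f"zero successful iterations at {point_id}")
        beta_err, gamma_err, logdelta_err = [], [], []
        baseline_err: dict[str, list[np.ndarray]] = {}
        for r in runs:
            if list(r.combat_fit.feature_names) != features:
                raise ValueError(f"feature mismatch at {point_id}")
            std = r.regression.beta_age.reindex(features).to_numpy() / silver_se
            beta_err.append(std - silver_beta / silver_se)
            g = r.combat_fit.gamma_star.loc[[s1, s2], features].to_numpy()
            d = np.log(r.combat_fit.delta_star.loc[[s1, s2], features].to_numpy())
            gamma_err.append(g - silver_gamma)
            logdelta_err.append(d - silver_logdelta)
            for kind, fit in r.baselines.items():
                e = (fit.beta_age.reindex(features).to_numpy() - silver_beta) / silver_se
                baseline_err.setdefault(kind, []).append(e)
        beta_err = np.asarray(beta_err)                  # (B, F)
        gamma_err = np.asarray(gamma_err)                # (B, 2, F)
        logdelta_err = np.asarray(logdelta_err)

        base = {"point_id": point_id, "total_n": p.total_n,
                "imbalance": p.imbalance, "shift": p.shift_years,
                "direction": p.direction, "n_runs": len(runs)}
        rows.append({**base, "metric": "rmse_std_beta_age", "site": "",
                     "value": _rmse_then_mean(beta_err)})
        for kind, errs in baseline_err.items():
            rows.append({**base, "metric": f"rmse_std_beta_age_{kind}", "site": "",
                         "value": _rmse_then_mean(np.asarray(errs))})
        for k, s in enumerate((s1, s2)):
            rows.append({**base, "metric": "rmse_gamma", "site": str(s),
                         "value": _rmse_then_mean(gamma_err[:, k, :])})
            rows.append({**base, "metric": "rmse_log_delta", "site": str(s),
                         "value": _rmse_then_mean(logdelta_err[:, k, :])})
        rows.append({**base, "metric": "rmse_gamma_diff", "site": "",
                     "value": _rmse_then_mean(gamma_err[:, 0, :] - gamma_err[:, 1, :])})
        rows.append({**base, "metric": "rmse_log_delta_diff", "site": "",
                     "value": _rmse_then_mean(logdelta_err[:, 0, :] - logdelta_err[:, 1, :])})
    if not rows:
        raise ValueError("no successful runs to score")
    return StabilityReport(long=pd.DataFrame(rows))


def tabulate_grid(report: StabilityReport, metric: str, shift: float,
                  site: str = "", direction: str = "pooled") -> pd.DataFrame:
    """One 2-D slice: total_n (rows) x imbalance (columns).

    ``direction='pooled'`` averages the two shift directions; cells with
    no feasible runs come out NaN.
    """
    df = report.long
    sel = (df["metric"] == metric) & (df["shift"] == shift) & (df["site"] == site)
    if direction != "pooled":
        sel &= df["direction"] == direction
    sub = df[sel]
    if sub.empty:
        raise ValueError(f"no rows for metric={metric!r}, shift={shift!r}, "
                         f"site={site!r}, direction={direction!r}")
    return sub.pivot_table(index="total_n", columns="imbalance",
                           values="value", aggfunc="mean")
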