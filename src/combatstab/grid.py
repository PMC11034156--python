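"""Bootstrap experiment grid: sample size x imbalance x covariate shift.

The stability experiment draws subcohorts from a two-site reference
("silver standard") cohort over a Cartesian grid of total sample size,
site-imbalance ratio (X:10) and engineered between-site mean-age
difference (covariate shift, years), harmonizes each subcohort and
refits the age-association model.  Sampling is without replacement; a
cell is feasible only if both sites keep at least 6 participants, the
per-site targets fit inside the site pools, and the target age shift is
attainable within +/-1 year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .combat import CombatFit, harmonize
from .data import FeatureTable
from .regression import RegressionFit, fit_feature_regressions

MIN_PER_SITE = 6
SHIFT_TOLERANCE = 1.0  # years

#: default total-sample-size levels: log-spaced below 108, step 18 above
DEFAULT_N_LEVELS = [12, 18, 24, 36, 48, 72, 96, 108, 126, 144, 162, 180,
                    198, 216, 234, 252, 270, 288, 306]
DEFAULT_IMBALANCE_LEVELS = list(range(1, 11))
DEFAULT_SHIFT_LEVELS = [0, 2, 4, 6, 8, 10]

DIRECTIONS = ("site2_older", "site1_older")


class ShiftUnattainableError(RuntimeError):
    """Rejection budget exhausted while targeting an age shift."""


def split_total(total_n: int, imbalance: int) -> tuple[int, int]:
    """(n_fixed, n_varying) for ratio ``imbalance``:10, varying site second.

    Round-half-away-from-zero on the varying site's exact share; the
    remainder goes to the fixed-denominator site.
    """
    exact = total_n * imbalance / (imbalance + 10.0)
    n_var = int(math.floor(exact + 0.5))
    return total_n - n_var, n_var


@dataclass
class ExperimentPoint:
    """One cell of the experimental grid."""

    total_n: int
    imbalance: int           # X in X:10
    shift_years: float
    direction: str           # 'none' | 'site1_older' | 'site2_older'
    n_fixed: int             # fixed-denominator site (site 1)
    n_var: int               # varying site (site 2)
    feasible: bool
    reason: str              # '' when feasible

    @property
    def point_id(self) -> str:
        return (f"N{self.total_n}_X{self.imbalance}"
                f"_S{self.shift_years:g}_{self.direction}")


@dataclass
class BootstrapRun:
    """One without-replacement draw at a grid cell."""

    point: ExperimentPoint
    iteration: int
    participant_ids: dict      # site -> list of ids
    achieved_shift: float      # years, oriented along the cell's direction
    seed: int

    def all_ids(self) -> list:
        out = []
        for ids in self.participant_ids.values():
            out.extend(ids)
        return out


@dataclass
class RunResult:
    """Everything recorded for one (cell, iteration) pipeline run."""

    run: BootstrapRun
    combat_fit: CombatFit | None
    regression: RegressionFit | None
    baselines: dict = field(default_factory=dict)  # model_kind -> RegressionFit
    status: str = "ok"
    error: str = ""


def _max_attainable_shift(ages_older: np.ndarray, ages_younger: np.ndarray,
                          n_older: int, n_younger: int) -> float:
    """Largest mean-age difference achievable by extreme selection."""
    top = np.sort(ages_older)[-n_older:]
    bottom = np.sort(ages_younger)[:n_younger]
    return float(top.mean() - bottom.mean())


def build_grid(cohort: FeatureTable,
               n_levels: list[int] | None = None,
               imbalance_levels: list[int] | None = None,
               shift_levels: list[float] | None = None) -> list[ExperimentPoint]:
    """Enumerate all grid cells with feasibility flags.

    Nonzero shifts are expanded into both directions.  Site 1 (first in
    the cohort's site order) is the fixed-denominator site; only site 2's
    count changes with the imbalance ratio.
    """
    n_levels = DEFAULT_N_LEVELS if n_levels is None else list(n_levels)
    imbalance_levels = (DEFAULT_IMBALANCE_LEVELS if imbalance_levels is None
                        else list(imbalance_levels))
    shift_levels = (DEFAULT_SHIFT_LEVELS if shift_levels is None
                    else list(shift_levels))
    if not n_levels or not imbalance_levels or not shift_levels:
        raise ValueError("level lists must be non-empty")
    sites = cohort.sites
    if len(sites) != 2:
        raise ValueError(f"cohort must have exactly 2 sites, got {len(sites)}")
    pools = cohort.n_per_site()
    ages = {s: cohort.covariates.loc[cohort.site_mask(s), "age"].to_numpy(float)
            for s in sites}

    points: list[ExperimentPoint] = []
    for total_n in n_levels:
        for x in imbalance_levels:
            n_fixed, n_var = split_total(total_n, x)
            for shift in shift_levels:
                dirs = ["none"] if shift == 0 else list(DIRECTIONS)
                for direction in dirs:
                    feasible, reason = True, ""
                    if min(n_fixed, n_var) < MIN_PER_SITE:
                        feasible, reason = False, "min-per-site"
                    elif n_fixed > pools[sites[0]] or n_var > pools[sites[1]]:
                        feasible, reason = False, "pool-exceeded"
                    elif shift > 0:
                        if direction == "site2_older":
                            max_shift = _max_attainable_shift(
                                ages[sites[1]], ages[sites[0]], n_var, n_fixed)
                        else:
                            max_shift = _max_attainable_shift(
                                ages[sites[0]], ages[sites[1]], n_fixed, n_var)
                        if max_shift < shift - SHIFT_TOLERANCE:
                            feasible, reason = False, "shift-unattainable"
                    points.append(ExperimentPoint(
                        total_n=total_n, imbalance=x, shift_years=float(shift),
                        direction=direction, n_fixed=n_fixed, n_var=n_var,
                        feasible=feasible, reason=reason))
    return points


def grid_manifest(points: list[ExperimentPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"point_id": p.point_id, "total_n": p.total_n, "imbalance": p.imbalance,
          "shift": p.shift_years, "direction": p.direction,
          "n_fixed": p.n_fixed, "n_var": p.n_var,
          "feasible": p.feasible, "reason": p.reason}
         for p in points]
    )


def sample_subcohort(cohort: FeatureTable, point: ExperimentPoint, seed: int,
                     max_attempts: int = 200) -> BootstrapRun:
    """Draw one without-replacement subcohort targeting the cell's shift.

    Per-site draws are exponentially age-tilted toward the per-site target
    means (inverse-probability weighting) and rejected until the realized
    mean-age difference is within one year of target.
    """
    if not point.feasible:
        raise ValueError(f"point {point.point_id} is infeasible ({point.reason})")
    sites = cohort.sites
    rng = np.random.default_rng(seed)
    targets = {sites[0]: point.n_fixed, sites[1]: point.n_var}
    pool_idx = {s: np.flatnonzero(cohort.site_mask(s)) for s in sites}
    ages = {s: cohort.covariates["age"].to_numpy(float)[pool_idx[s]] for s in sites}
    mu0 = float(cohort.covariates["age"].mean())

    # signed target: positive when site 2 (varying) should be older
    if point.direction == "site2_older":
        signed = point.shift_years
    elif point.direction == "site1_older":
        signed = -point.shift_years
    else:
        signed = 0.0
    target_mean = {sites[0]: mu0 - signed / 2.0, sites[1]: mu0 + signed / 2.0}

    for _ in range(max_attempts):
        chosen = {}
        for s in sites:
            a = ages[s]
            var = float(np.var(a))
            lam = 0.0 if var == 0 else (target_mean[s] - float(np.mean(a))) / var
            w = np.exp(lam * (a - a.mean()))
            w /= w.sum()
            take = rng.choice(len(a), size=targets[s], replace=False, p=w)
            chosen[s] = pool_idx[s][np.sort(take)]
        mean_age = {s: float(cohort.covariates["age"].iloc[chosen[s]].mean())
                    for s in sites}
        achieved = mean_age[sites[1]] - mean_age[sites[0]]
        if abs(achieved - signed) <= SHIFT_TOLERANCE:
            ids = {s: cohort.covariates["participant_id"].iloc[chosen[s]].tolist()
                   for s in sites}
            oriented = achieved if point.direction != "site1_older" else -achieved
            return BootstrapRun(point=point, iteration=0, participant_ids=ids,
                                achieved_shift=oriented, seed=seed)
    raise ShiftUnattainableError(
        f"could not hit shift {point.shift_years:g}y (+/-{SHIFT_TOLERANCE}y) at "
        f"{point.point_id} in {max_attempts} attempts"
    )


def subcohort_table(cohort: FeatureTable, run: BootstrapRun) -> FeatureTable:
    """Materialize the participant rows of a bootstrap draw, site 1 first."""
    ids = run.all_ids()
    lookup = pd.Series(np.arange(cohort.n_participants),
                       index=cohort.covariates["participant_id"])
    return cohort.subset(lookup.loc[ids].to_numpy())


def derive_seed(master_seed: int, point_index: int, iteration: int) -> int:
    """Deterministic per-run seed below 2**31."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(point_index, iteration))
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(cohort: FeatureTable, grid: list[ExperimentPoint], B: int,
                   covariates: list[str] | None = None, master_seed: int = 0,
                   baselines: tuple[str, ...] = (),
                   regression_all_covariates: bool = False) -> list[RunResult]:
    """Sample, harmonize and regress at every feasible cell, B times each.

    Every run's seed derives deterministically from ``master_seed`` and
    its (cell, iteration) coordinates, so any single run can be
    reproduced in isolation.  Per-run failures are recorded, not raised.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    results: list[RunResult] = []
    for i, point in enumerate(grid):
        if not point.feasible:
            continue
        for b in range(1, B + 1):
            seed = derive_seed(master_seed, i, b)
            try:
                run = sample_subcohort(cohort, point, seed)
                run.iteration = b
                sub = subcohort_table(cohort, run)
                harmonized, fit = harmonize(sub, covariates)
                reg = fit_feature_regressions(
                    harmonized, "combat_ols", all_covariates=regression_all_covariates)
                extra = {}
                for kind in baselines:
                    extra[kind] = fit_feature_regressions(
                        sub, kind, all_covariates=regression_all_covariates)
                results.append(RunResult(run=run, combat_fit=fit, regression=reg,
                                         baselines=extra))
            except ShiftUnattainableError as exc:
                stub = BootstrapRun(point=point, iteration=b, participant_ids={},
                                    achieved_shift=float("nan"), seed=seed)
                results.append(RunResult(run=stub, combat_fit=None, regression=None,
                                         status="skipped", error=str(exc)))
            except Exception as exc:
                stub = BootstrapRun(point=point, iteration=b, participant_ids={},
                                    achieved_shift=float("nan"), seed=seed)
                results.append(RunResult(run=stub, combat_fit=None, regression=None,
                                         status="error", error=str(exc)))
    return results
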