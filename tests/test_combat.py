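"""ComBat core: constrained standardization, EB shrinkage, adjustment."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import combatstab as cs
from combatstab.combat import fit_standardization, moments_estimate

from conftest import make_table


def constrained_ls_oracle(table, covariate_names):
    """Independent constrained least squares via reparameterization.

    Substituting gamma_1 = -(n2/n1) gamma_2 into the identifiability
    constraint turns the problem into ordinary least squares on
    [1 | X | c] with c_i = 1{site2} - (n2/n1) 1{site1}.
    """
    from combatstab.combat import build_design

    X, _ = build_design(table, covariate_names)
    sites = table.sites
    n = table.n_per_site()
    n1, n2 = n[sites[0]], n[sites[1]]
    is2 = table.site_mask(sites[1]).astype(float)
    c = is2 - (n2 / n1) * (1.0 - is2)
    design = np.column_stack([np.ones(table.n_participants), X, c])
    coef, *_ = np.linalg.lstsq(design, table.values, rcond=None)
    alpha = coef[0]
    beta = coef[1:-1].T
    gamma2 = coef[-1]
    gamma1 = -(n2 / n1) * gamma2
    resid = table.values - design @ coef
    sigma2 = np.mean(resid**2, axis=0)
    return alpha, beta, np.vstack([gamma1, gamma2]), sigma2


class TestStandardization:
    def test_constraint_holds_on_random_instances(self):
        """Sample-size-weighted site effects sum to zero per feature."""
        rng = np.random.default_rng(0)
        for k in range(25):
            t = make_table(n1=int(rng.integers(6, 20)), n2=int(rng.integers(6, 20)),
                           n_features=int(rng.integers(1, 6)), seed=k)
            fit = fit_standardization(t, ["age", "sex"])
            w = np.array([fit.n_per_site[s] for s in fit.sites], float)
            resid = w @ fit.gamma_hat.to_numpy()
            assert np.abs(resid).max() < 1e-8 * max(1.0, np.abs(t.values).max())

    def test_duplicated_site_data_gives_zero_site_effects(self):
        """Two sites with identical data: symmetry forces gamma_hat = 0
        and per-feature zero mean of Z."""
        rng = np.random.default_rng(1)
        half = rng.normal(0.5, 0.05, size=(10, 4))
        t = make_table(n1=10, n2=10, values=np.vstack([half, half]), seed=1)
        fit = fit_standardization(t, [])
        np.testing.assert_allclose(fit.gamma_hat.to_numpy(), 0.0, atol=1e-10)
        np.testing.assert_allclose(fit.Z.mean(axis=0), 0.0, atol=1e-10)

    def test_matches_brute_force_constrained_least_squares(self):
        """Hand-reparameterized normal-equations solution on a tiny instance."""
        t = make_table(n1=3, n2=3, n_features=1, seed=7)
        fit = fit_standardization(t, ["age"])
        alpha, beta, gamma, sigma2 = constrained_ls_oracle(t, ["age"])
        np.testing.assert_allclose(fit.alpha_hat, alpha, atol=1e-8)
        np.testing.assert_allclose(fit.beta_hat, beta, atol=1e-8)
        np.testing.assert_allclose(fit.gamma_hat.to_numpy(), gamma, atol=1e-8)
        np.testing.assert_allclose(fit.sigma_hat**2, sigma2, atol=1e-10)

    def test_constant_feature_rejected_by_name(self):
        t = make_table(n1=8, n2=8, n_features=2, seed=2)
        t.values[:, 1] = 0.5
        with pytest.raises(ValueError, match="feat_002"):
            fit_standardization(t, ["age"])

    def test_single_site_rejected(self):
        t = make_table(n1=10, n2=0, seed=3)
        t.covariates["site"] = "site1"
        with pytest.raises(ValueError, match="2 sites"):
            fit_standardization(t, ["age"])

    def test_constant_covariate_dropped_with_warning(self):
        t = make_table(n1=8, n2=8, seed=4)
        t.covariates["diagnosis"] = 0
        with pytest.warns(UserWarning, match="diagnosis"):
            fit = fit_standardization(t, ["age", "diagnosis"])
        assert fit.design_columns == ["age"]


class TestEmpiricalBayes:
    def test_identical_site_means_collapse_to_the_common_value(self):
        """When every feature's standardized site mean is the same, the
        shrinkage target equals every observation and gamma_star is that
        common value exactly."""
        t = make_table(n1=10, n2=10, n_features=4, seed=5)
        fit = fit_standardization(t, [])
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((20, 4)) * np.array([0.5, 1.0, 2.0, 3.0])
        for s in fit.sites:
            m = t.site_mask(s)
            Z[m] = Z[m] - Z[m].mean(axis=0) + 0.7  # all site means exactly 0.7
        fit.Z = Z
        fit = cs.eb_estimate(fit, t)
        np.testing.assert_allclose(fit.gamma_star.to_numpy(), 0.7, atol=1e-10)

    def test_shrinkage_is_a_contraction(self, silver):
        """gamma_star lies between the raw standardized site mean and the
        cross-feature prior mean, for every (site, feature)."""
        table, _ = silver
        _, fit = cs.harmonize(table)
        for s in fit.sites:
            Zs = fit.Z[table.site_mask(s)]
            g_hat = Zs.mean(axis=0)
            g_bar = g_hat.mean()
            g_star = fit.gamma_star.loc[s].to_numpy()
            lo = np.minimum(g_hat, g_bar) - 1e-10
            hi = np.maximum(g_hat, g_bar) + 1e-10
            assert np.all((g_star >= lo) & (g_star <= hi))

    def test_null_site_effects_shrink_toward_zero_and_one(self):
        """Standard-normal data within each site: gamma_star near 0,
        delta_star near 1, tighter than the raw per-site moments."""
        rng = np.random.default_rng(11)
        t = make_table(n1=150, n2=150, n_features=60,
                       values=rng.standard_normal((300, 60)), seed=11)
        _, fit = cs.harmonize(t, [])
        assert np.abs(fit.gamma_star.to_numpy()).max() < 0.35
        assert np.abs(fit.delta_star.to_numpy() - 1).max() < 0.35

    def test_too_few_features_rejected(self):
        t = make_table(n1=10, n2=10, n_features=1, seed=6)
        fit = fit_standardization(t, [])
        with pytest.raises(ValueError, match="2 features"):
            cs.eb_estimate(fit, t)


class TestAdjustment:
    def test_identity_when_gamma_zero_delta_one(self):
        t = make_table(n1=8, n2=8, n_features=3, seed=8)
        fit = fit_standardization(t, ["age"])
        shape = (2, 3)
        fit.gamma_star = pd.DataFrame(np.zeros(shape), index=fit.sites,
                                      columns=fit.feature_names)
        fit.delta_star = pd.DataFrame(np.ones(shape), index=fit.sites,
                                      columns=fit.feature_names)
        out = cs.adjust(fit, t)
        np.testing.assert_allclose(out.values, t.values, rtol=0, atol=1e-12)

    def test_no_eb_without_covariates_equalizes_site_moments(self):
        """Exact location/scale matching: per-site means and variances of
        the harmonized features agree across sites to machine precision."""
        t = make_table(n1=12, n2=20, n_features=4, seed=9)
        out, fit = cs.harmonize(t, [], mode="no_eb")
        m, v = [], []
        for s in fit.sites:
            sub = out.values[t.site_mask(s)]
            m.append(sub.mean(axis=0))
            v.append(sub.var(axis=0, ddof=1))
        np.testing.assert_allclose(m[0], m[1], atol=1e-10)
        np.testing.assert_allclose(v[0], v[1], atol=1e-10)

    def test_doubling_delta_star_halves_residual_spread(self):
        t = make_table(n1=10, n2=10, n_features=3, seed=10)
        fit = fit_standardization(t, [])
        fit = moments_estimate(fit, t)
        base = cs.adjust(fit, t)
        s0 = fit.sites[0]
        mask = t.site_mask(s0)
        spread_before = (base.values[mask] - fit.stand_mean[mask]).std(axis=0)
        fit.delta_star.loc[s0] *= 2.0
        doubled = cs.adjust(fit, t)
        spread_after = (doubled.values[mask] - fit.stand_mean[mask]).std(axis=0)
        np.testing.assert_allclose(spread_after, spread_before / 2, rtol=1e-10)

    def test_nonpositive_delta_rejected(self):
        t = make_table(n1=8, n2=8, seed=12)
        fit = fit_standardization(t, [])
        fit = moments_estimate(fit, t)
        fit.delta_star.iloc[0, 0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            cs.adjust(fit, t)


class TestHarmonize:
    def test_unknown_mode_rejected(self):
        t = make_table(seed=13)
        with pytest.raises(ValueError, match="mode"):
            cs.harmonize(t, [], mode="bootstrap")

    def test_idempotence_second_pass_is_nearly_a_no_op(self, silver):
        table, _ = silver
        once, _ = cs.harmonize(table)
        _, fit2 = cs.harmonize(once)
        assert np.abs(fit2.gamma_star.to_numpy()).max() < 0.05
        assert np.abs(fit2.delta_star.to_numpy() - 1).max() < 0.05

    def test_site_mean_gap_shrinks_by_over_95_percent(self):
        """Injected additive site shift is removed almost entirely."""
        prior = (cs.SitePrior(gamma_mean=0.05, gamma_var=1e-4,
                              delta_shape=25, delta_rate=24),
                 cs.SitePrior(gamma_mean=-0.05, gamma_var=1e-4,
                              delta_shape=25, delta_rate=26))
        config = cs.CohortConfig(seed=21, site_prior=prior)
        table, _ = cs.generate_matched_cohort(config)
        out, fit = cs.harmonize(table)
        m1, m2 = table.site_mask("site1"), table.site_mask("site2")
        raw_gap = np.abs(table.values[m1].mean(0) - table.values[m2].mean(0))
        harm_gap = np.abs(out.values[m1].mean(0) - out.values[m2].mean(0))
        assert harm_gap.mean() < 0.05 * raw_gap.mean()

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_sva_combat_reference_implementation(self, tmp_path):
        """Full parametric EB pipeline agrees with Bioconductor sva::ComBat
        on a small two-site cohort (independent reference implementation)."""
        config = cs.CohortConfig(seed=11, n_per_site=40, n_features=8)
        table, _ = cs.generate_cohort(config)
        harmonized, _ = cs.harmonize(table, ["age", "sex"], conv=1e-8)

        dat = tmp_path / "dat.csv"
        covs = tmp_path / "covs.csv"
        out = tmp_path / "sva_out.csv"
        pd.DataFrame(table.values.T,
                     columns=table.covariates["participant_id"]).to_csv(dat, index=False)
        table.covariates[["site", "age", "sex"]].to_csv(covs, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(f"""
suppressMessages(library(sva))
dat <- as.matrix(read.csv("{dat}", check.names=FALSE))
covs <- read.csv("{covs}")
mod <- model.matrix(~ age + sex, data=covs)
res <- ComBat(dat=dat, batch=covs$site, mod=mod, par.prior=TRUE, prior.plots=FALSE)
write.csv(res, "{out}", row.names=FALSE)
""")
        proc = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        sva = pd.read_csv(out).to_numpy().T
        np.testing.assert_allclose(harmonized.values, sva, atol=2e-3 * 0.5)
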