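"""Multilevel negative-binomial model: likelihood, fitting, IRRs, study runner."""

import json
import os
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import gammaln, logsumexp

from actigeo import model as M


def _sim_table(rng, G=40, nper=10, beta=(1.0, 0.3, 0.8), theta=3.0, sd0=0.0, sd1=0.0):
    n = G * nper
    tab = pd.DataFrame(
        {
            "participant_id": np.repeat([f"P{i:03d}" for i in range(G)], nper),
            "day_index": np.tile(np.arange(1, nper + 1), G),
            "x1": rng.normal(size=n),
            "is_home_da": rng.integers(0, 2, n),
        }
    )
    tc = tab["day_index"] - tab["day_index"].mean()
    b = rng.multivariate_normal([0, 0], [[sd0**2, 0], [0, sd1**2]], size=G)
    eta = (
        beta[0]
        + beta[1] * tab["x1"]
        + beta[2] * tab["is_home_da"]
        + b[:, 0].repeat(nper)
        + b[:, 1].repeat(nper) * tc
    )
    mu = np.exp(eta)
    tab["pa_minutes"] = rng.negative_binomial(theta, theta / (theta + mu))
    return tab


SPEC2 = M.ModelSpec(outcome="pa_minutes", fixed=("x1", "is_home_da"))


class TestLikelihood:
    def test_agq_matches_dense_grid_integration(self, rng):
        """Quadrature marginal loglik vs brute-force 2-D grid, tiny instance."""
        G, nobs = 5, 4
        rows = []
        for i in range(G):
            for k in range(1, nobs + 1):
                rows.append(
                    {
                        "participant_id": f"P{i}",
                        "day_index": k,
                        "x1": rng.normal(),
                        "y": int(rng.poisson(5)),
                    }
                )
        tab = pd.DataFrame(rows)
        X = np.column_stack([np.ones(len(tab)), tab["x1"]])
        y = tab["y"].to_numpy(float)
        _, gidx = np.unique(tab["participant_id"], return_inverse=True)
        t = tab["day_index"].to_numpy(float)
        t = t - t.mean()
        Z = np.column_stack([np.ones_like(t), t])
        params = np.array([1.4, 0.3, np.log(3.0), np.log(0.4), np.log(0.2), np.arctanh(0.3)])

        ll_agq = M.nb_glmm_loglik(
            params, X, y, Z, gidx, G, "intercept_slope", M.FitControl(nagq=25)
        )

        beta, theta = params[:2], np.exp(params[2])
        sd0, sd1, rho = np.exp(params[3]), np.exp(params[4]), np.tanh(params[5])
        Sig = np.array([[sd0**2, rho * sd0 * sd1], [rho * sd0 * sd1, sd1**2]])
        Sinv = np.linalg.inv(Sig)
        sdet = np.linalg.slogdet(Sig)[1]
        eta0 = X @ beta
        ng = 601
        b0g = np.linspace(-8 * sd0, 8 * sd0, ng)
        b1g = np.linspace(-8 * sd1, 8 * sd1, ng)
        db = (b0g[1] - b0g[0]) * (b1g[1] - b1g[0])
        B0, B1 = np.meshgrid(b0g, b1g, indexing="ij")
        const = gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
        total = 0.0
        for g in range(G):
            m = gidx == g
            eta = eta0[m][:, None, None] + B0[None] + t[m][:, None, None] * B1[None]
            mu = np.exp(eta)
            ll = (
                const[m][:, None, None]
                + theta * (np.log(theta) - np.log(theta + mu))
                + y[m][:, None, None] * (eta - np.log(theta + mu))
            )
            f = (
                ll.sum(axis=0)
                - 0.5 * (B0 * (Sinv[0, 0] * B0 + Sinv[0, 1] * B1) + B1 * (Sinv[1, 0] * B0 + Sinv[1, 1] * B1))
                - np.log(2 * np.pi)
                - 0.5 * sdet
            )
            total += logsumexp(f) + np.log(db)
        assert abs(ll_agq - total) < 1e-6

    def test_laplace_close_to_quadrature(self, rng):
        tab = _sim_table(rng, sd0=0.3, sd1=0.05)
        f1 = M.fit_nb_glmm(tab, SPEC2, M.FitControl(nagq=1))
        f7 = M.fit_nb_glmm(tab, SPEC2, M.FitControl(nagq=7))
        assert np.allclose(f1.beta, f7.beta, atol=0.05)


class TestOracles:
    def test_zero_re_matches_plain_nb_regression(self):
        """With the RE variance pinned at ~0 the marginal model reduces to NB."""
        rng = np.random.default_rng(3)
        tab = _sim_table(rng, G=40, nper=20)
        ctrl = M.FitControl(nagq=7, log_sd_bounds=(-8.0, -8.0), gtol=1e-8)
        fit = M.fit_nb_glmm(tab, SPEC2, ctrl)
        X = sm.add_constant(tab[["x1", "is_home_da"]].to_numpy(float))
        oracle = sm.NegativeBinomial(tab["pa_minutes"].to_numpy(), X).fit(
            disp=0, maxiter=200, gtol=1e-10
        )
        assert np.abs(fit.beta.to_numpy() - oracle.params[:3]).max() < 1e-4
        assert abs(fit.dispersion - 1 / oracle.params[-1]) / fit.dispersion < 1e-3

    def test_poisson_limit_matches_poisson_glm(self):
        """Poisson-simulated data: dispersion diverges, betas match Poisson GLM."""
        rng = np.random.default_rng(4)
        tab = _sim_table(rng, G=40, nper=20)
        eta = 1.0 + 0.3 * tab["x1"] + 0.8 * tab["is_home_da"]
        tab["pa_minutes"] = rng.poisson(np.exp(eta))
        ctrl = M.FitControl(nagq=7, log_sd_bounds=(-8.0, -8.0))
        fit = M.fit_nb_glmm(tab, SPEC2, ctrl)
        oracle = sm.GLM(
            tab["pa_minutes"].to_numpy(),
            sm.add_constant(tab[["x1", "is_home_da"]].to_numpy(float)),
            family=sm.families.Poisson(),
        ).fit()
        # the likelihood is flat in theta near the Poisson boundary: "large"
        # means negligible overdispersion (mu/theta < ~10% at these means) and
        # no significant likelihood-ratio improvement over the Poisson fit
        # (NB nests Poisson, so the gap is >= 0 by construction)
        assert fit.dispersion > 50
        lr = 2 * (fit.loglik - oracle.llf)
        assert 0 <= lr < 3.84
        # betas differ from the Poisson fit by O(1/theta): far below the
        # sampling SE (~0.03 here)
        assert np.abs(fit.beta.to_numpy() - oracle.params).max() < 0.01

    def test_matches_glmmtmb_reference(self):
        """Independent cross-check: R glmmTMB (Laplace) on the same data."""
        rng = np.random.default_rng(5)
        tab = _sim_table(rng, G=60, nper=10, beta=(1.2, 0.3, 0.9), sd0=0.3, sd1=0.05)
        fit = M.fit_nb_glmm(tab, SPEC2, M.FitControl(nagq=1))
        tc = tab["day_index"] - tab["day_index"].mean()
        with tempfile.TemporaryDirectory() as td:
            csv = os.path.join(td, "d.csv")
            tab.assign(day_c=tc).to_csv(csv, index=False)
            script = os.path.join(td, "s.R")
            with open(script, "w") as fh:
                fh.write(
                    'suppressMessages(library(glmmTMB))\n'
                    f'd <- read.csv("{csv}")\n'
                    "m <- glmmTMB(pa_minutes ~ x1 + is_home_da + (1 + day_c | participant_id),"
                    " data=d, family=nbinom2)\n"
                    "cat(jsonlite::toJSON(list(beta=as.numeric(fixef(m)$cond),"
                    " theta=sigma(m)), digits=10))\n"
                )
            out = subprocess.run(
                ["Rscript", script], capture_output=True, text=True, timeout=600
            )
            ref = json.loads(out.stdout)
        assert np.abs(fit.beta.to_numpy() - np.asarray(ref["beta"])).max() < 0.02
        assert abs(fit.dispersion - ref["theta"][0]) / fit.dispersion < 0.02


class TestFitMechanics:
    def test_reproducible_to_machine_precision(self, rng):
        tab = _sim_table(rng, sd0=0.3, sd1=0.05)
        a = M.fit_nb_glmm(tab, SPEC2, M.FitControl(nagq=3))
        b = M.fit_nb_glmm(tab, SPEC2, M.FitControl(nagq=3))
        np.testing.assert_array_equal(a.params_packed, b.params_packed)

    def test_day_index_shift_leaves_slopes_unchanged(self, rng):
        """Centering makes exposure coefficients invariant to day-index origin."""
        tab = _sim_table(rng, sd0=0.3, sd1=0.05)
        shifted = tab.assign(day_index=tab["day_index"] + 100)
        a = M.fit_nb_glmm(tab, SPEC2, M.FitControl(nagq=3))
        b = M.fit_nb_glmm(shifted, SPEC2, M.FitControl(nagq=3))
        np.testing.assert_allclose(
            a.beta[["x1", "is_home_da"]], b.beta[["x1", "is_home_da"]], atol=1e-8
        )

    def test_collinear_columns_named(self, rng):
        tab = _sim_table(rng)
        tab["x2"] = 2 * tab["x1"]
        with pytest.raises(ValueError, match="x2"):
            M.fit_nb_glmm(tab, M.ModelSpec(outcome="pa_minutes", fixed=("x1", "x2")))

    def test_non_integer_outcome_rejected(self, rng):
        tab = _sim_table(rng)
        tab["pa_minutes"] = tab["pa_minutes"] + 0.5
        with pytest.raises(ValueError, match="integer"):
            M.fit_nb_glmm(tab, SPEC2)

    def test_missing_demographics_complete_case_logged(self, rng):
        tab = _sim_table(rng)
        tab.loc[:9, "x1"] = np.nan
        fit = M.fit_nb_glmm(tab, SPEC2, M.FitControl(nagq=1))
        assert fit.n_dropped_missing == 10
        assert fit.n_obs == len(tab) - 10

    def test_categorical_reference_levels(self, rng):
        tab = _sim_table(rng)
        tab["gentrification_class"] = rng.choice(
            ["high_ses", "low_ses_not_gentrified", "gentrified"], size=len(tab)
        )
        spec = M.ModelSpec(outcome="pa_minutes", fixed=("x1", "gentrification_class"))
        X, _, _ = M.build_design(tab, spec)
        assert "gentrification_class[low_ses_not_gentrified]" in X.columns
        assert "gentrification_class[gentrified]" in X.columns
        assert "gentrification_class[high_ses]" not in X.columns


class TestIrrTable:
    def test_zero_beta_gives_unit_irr_with_symmetric_ci(self):
        fit = M.NBGLMMFit(
            beta=pd.Series([0.0], index=["x"]),
            vcov=pd.DataFrame([[0.04]], index=["x"], columns=["x"]),
            re_cov=np.eye(2),
            dispersion=2.0,
            loglik=0.0,
            converged=True,
            n_obs=10,
            n_groups=2,
            spec=SPEC2,
        )
        t = M.irr_table(fit).iloc[0]
        assert t["irr"] == 1.0
        np.testing.assert_allclose(np.log(t["ci_lo"]), -np.log(t["ci_hi"]))

    def test_zero_se_collapses_ci(self):
        fit = M.NBGLMMFit(
            beta=pd.Series([np.log(1.3)], index=["x"]),
            vcov=pd.DataFrame([[0.0]], index=["x"], columns=["x"]),
            re_cov=np.eye(2),
            dispersion=2.0,
            loglik=0.0,
            converged=True,
            n_obs=10,
            n_groups=2,
            spec=SPEC2,
        )
        t = M.irr_table(fit).iloc[0]
        np.testing.assert_allclose([t["ci_lo"], t["irr"], t["ci_hi"]], 1.3)

    def test_log_ci_equidistant_from_estimate(self, rng):
        tab = _sim_table(rng)
        fit = M.fit_nb_glmm(tab, SPEC2, M.FitControl(nagq=1))
        t = M.irr_table(fit)
        np.testing.assert_allclose(
            np.log(t["irr"]) - np.log(t["ci_lo"]), np.log(t["ci_hi"]) - np.log(t["irr"])
        )
        assert ((t["ci_lo"] <= t["irr"]) & (t["irr"] <= t["ci_hi"])).all()


class TestRunStudy:
    def test_bookkeeping_two_cities_two_outcomes(self, rng):
        tables = {}
        for c in ("cityA", "cityB"):
            t = _sim_table(rng, G=20, nper=6, sd0=0.2, sd1=0.02)
            t["mvpa_minutes"] = rng.binomial(t["pa_minutes"], 0.3)
            t["minutes_total"] = t["pa_minutes"] + 10
            t["da_id"] = rng.choice(["DA0", "DA1", "DA2"], size=len(t))
            t["can_ale_q"] = t["da_id"].map({"DA0": 1, "DA1": 3, "DA2": 5})
            t["urban_compactness"] = t["da_id"].map({"DA0": -1.0, "DA1": 0.0, "DA2": 1.0})
            tables[c] = t
        spec = M.ModelSpec(fixed=("x1", "is_home_da"))
        report = M.run_study(tables, dwell_threshold=5, spec=spec, control=M.FitControl(nagq=1))
        main = [k for k in report.fits if k[2] == "main"]
        sens = [k for k in report.fits if k[2] == "sensitivity"]
        assert len(main) == 4 and len(sens) == 4
        assert set(report.exposure_corr) == {"cityA", "cityB"}

    def test_zero_threshold_sensitivity_equals_main(self, rng):
        t = _sim_table(rng, G=20, nper=6, sd0=0.2, sd1=0.02)
        t["mvpa_minutes"] = rng.binomial(t["pa_minutes"], 0.3)
        t["minutes_total"] = t["pa_minutes"] + 10
        t["da_id"] = "DA0"
        spec = M.ModelSpec(fixed=("x1", "is_home_da"))
        report = M.run_study(
            {"c": t}, outcomes=("pa_minutes",), dwell_threshold=0, spec=spec,
            control=M.FitControl(nagq=1),
        )
        a = report.fits[("c", "pa_minutes", "main")]
        b = report.fits[("c", "pa_minutes", "sensitivity")]
        np.testing.assert_array_equal(a.params_packed, b.params_packed)

    def test_failing_stratum_reported_not_fatal(self, rng):
        good = _sim_table(rng, G=20, nper=6, sd0=0.2, sd1=0.02)
        good["mvpa_minutes"] = rng.binomial(good["pa_minutes"], 0.3)
        good["minutes_total"] = good["pa_minutes"] + 10
        good["da_id"] = "DA0"
        bad = good.copy()
        bad["x1"] = 1.0  # constant: collinear with the intercept
        spec = M.ModelSpec(fixed=("x1", "is_home_da"))
        report = M.run_study(
            {"good": good, "bad": bad}, outcomes=("pa_minutes",), spec=spec,
            control=M.FitControl(nagq=1),
        )
        assert ("good", "pa_minutes", "main") in report.fits
        assert ("bad", "pa_minutes", "main") in report.errors
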