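"""Cox model fits: oracle agreement, robust variance, frailty behaviour."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from cmrctsim import _ppl
from cmrctsim.cox import (
    FitError,
    fit_cox,
    fit_cox_gamma_frailty,
    fit_cox_lognormal_frailty,
    fit_cox_marginal,
)

from conftest import make_clustered_survival


class TestPartialLikelihoodOracle:
    def test_six_subject_brute_force(self):
        # hand-checkable data: distinct times, explicit partial likelihood
        data = pd.DataFrame({
            "cluster": [0, 0, 1, 1, 2, 2],
            "x": [1, 0, 1, 0, 1, 0],
            "y": [2.0, 1.0, 4.0, 3.0, 6.0, 5.0],
            "c": [0, 0, 1, 0, 0, 1],
        })
        x = data["x"].to_numpy()
        y = data["y"].to_numpy()
        d = 1 - data["c"].to_numpy()

        def neg_log_pl(beta):
            ll = 0.0
            for i in np.flatnonzero(d):
                risk = y >= y[i]
                ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
            return -ll

        brute = minimize_scalar(neg_log_pl, bounds=(-5, 5), method="bounded",
                                options={"xatol": 1e-10})
        fit = fit_cox_marginal(data, ["x"], robust=False)
        assert fit.coef[0] == pytest.approx(brute.x, abs=1e-6)

    def test_score_vanishes_at_solution(self, clustered_data):
        fit = fit_cox_marginal(clustered_data, ["x"], robust=False)
        sd = _ppl.SurvSorted(
            clustered_data["y"], 1 - clustered_data["c"], clustered_data[["x"]].values
        )
        _, grad, _ = _ppl._ngh(sd, fit.coef, None)
        assert np.abs(grad).max() < 1e-6

    def test_time_scaling_invariance(self, clustered_data):
        fit1 = fit_cox_marginal(clustered_data, ["x"], robust=False)
        scaled = clustered_data.assign(y=clustered_data["y"] * 3.7)
        fit2 = fit_cox_marginal(scaled, ["x"], robust=False)
        assert fit1.coef[0] == pytest.approx(fit2.coef[0], abs=1e-8)


class TestAgainstLifelines:
    def test_coef_and_se(self, clustered_data):
        lifelines = pytest.importorskip("lifelines")
        fit = fit_cox_marginal(clustered_data, ["x"], robust=False)
        cph = lifelines.CoxPHFitter().fit(
            clustered_data.assign(e=1 - clustered_data["c"])[["x", "y", "e"]],
            "y", "e",
        )
        assert fit.coef[0] == pytest.approx(cph.params_["x"], abs=1e-5)
        assert fit.se[0] == pytest.approx(cph.standard_errors_["x"], rel=1e-4)

    def test_cluster_robust_se(self, clustered_data):
        lifelines = pytest.importorskip("lifelines")
        fit = fit_cox_marginal(clustered_data, ["x"], robust=True)
        cph = lifelines.CoxPHFitter().fit(
            clustered_data.assign(e=1 - clustered_data["c"]),
            "y", "e", cluster_col="cluster", robust=True, formula="x",
        )
        assert fit.se[0] == pytest.approx(cph.standard_errors_["x"], rel=1e-4)


@pytest.fixture(scope="module")
def r_fits(tmp_path_factory, clustered_data):
    """Independent oracle: survival::coxph frailty fits at fixed variance."""
    path = tmp_path_factory.mktemp("r") / "data.csv"
    clustered_data.assign(d=1 - clustered_data["c"]).to_csv(path, index=False)
    script = textwrap.dedent(f"""
        library(survival)
        df <- read.csv("{path}")
        f1 <- coxph(Surv(y, d) ~ x + frailty.gaussian(cluster, theta=0.25),
                    data=df, ties="breslow")
        f2 <- coxph(Surv(y, d) ~ x + frailty.gamma(cluster, theta=0.25),
                    data=df, ties="breslow")
        cat(coef(f1)[1], coef(f2)[1], sep="\\n")
    """)
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    gauss, gamma = map(float, out.stdout.split())
    return gauss, gamma


class TestAgainstRSurvival:
    def test_lognormal_coef_at_fixed_theta(self, clustered_data, r_fits):
        fit = fit_cox_lognormal_frailty(clustered_data, ["x"], theta=0.25)
        assert fit.coef[0] == pytest.approx(r_fits[0], abs=1e-4)

    def test_gamma_coef_at_fixed_theta(self, clustered_data, r_fits):
        fit = fit_cox_gamma_frailty(clustered_data, ["x"], theta=0.25)
        assert fit.coef[0] == pytest.approx(r_fits[1], abs=1e-4)


class TestFrailtyBehaviour:
    @pytest.mark.parametrize("fitter", [fit_cox_lognormal_frailty, fit_cox_gamma_frailty])
    def test_no_cluster_variation_collapses_to_plain_cox(self, fitter):
        data = make_clustered_survival(seed=11, sigma2_u=0.0, K=15, J=40)
        frail = fitter(data, ["x"])
        plain = fit_cox_marginal(data, ["x"], robust=False)
        assert frail.frailty_variance == pytest.approx(0.0, abs=0.02)
        assert frail.coef[0] == pytest.approx(plain.coef[0], abs=0.02)

    def test_gamma_close_to_lognormal_on_shared_frailty_data(self):
        data = make_clustered_survival(seed=12, sigma2_u=0.3, K=30, J=40)
        ln = fit_cox_lognormal_frailty(data, ["x"])
        gm = fit_cox_gamma_frailty(data, ["x"])
        assert gm.coef[0] == pytest.approx(ln.coef[0], rel=0.05)

    def test_single_cluster_unidentifiable(self):
        data = make_clustered_survival(seed=13, K=2, J=50).query("cluster == 0")
        with pytest.raises(FitError):
            fit_cox_lognormal_frailty(data, ["x"])

    def test_conditional_at_least_marginal_magnitude(self):
        # non-collapsibility: the within-cluster (conditional) effect is at
        # least as large in magnitude as the population-averaged one; the
        # attenuation is moderate at these frailty variances
        diffs = []
        for seed in range(5):
            data = make_clustered_survival(seed=seed, sigma2_u=0.3, K=25, J=50)
            ln = fit_cox_lognormal_frailty(data, ["x"])
            mg = fit_cox_marginal(data, ["x"])
            diffs.append(abs(ln.coef[0]) - abs(mg.coef[0]))
            assert abs(ln.coef[0] - mg.coef[0]) < 0.35 * abs(mg.coef[0])
        assert np.mean(diffs) > -0.005

    def test_robust_se_exceeds_model_se_on_clustered_data(self):
        # cluster-level covariate + shared frailty: positive within-cluster
        # correlation inflates the sandwich variance on average
        ratios = []
        for seed in range(8):
            data = make_clustered_survival(
                seed=seed, K=20, J=40, sigma2_u=0.4, subject_level_x=False
            )
            robust = fit_cox_marginal(data, ["x"], robust=True)
            model = fit_cox_marginal(data, ["x"], robust=False)
            ratios.append(robust.se[0] / model.se[0])
        assert np.mean(ratios) > 1.1

    def test_frailty_variance_recovery(self):
        # correctly specified lognormal model recovers sigma2_u
        thetas = []
        for seed in range(4):
            data = make_clustered_survival(
                seed=seed + 100, K=150, J=30, sigma2_u=0.2, beta=-0.32, horizon=12.0
            )
            fit = fit_cox_lognormal_frailty(data, ["x"])
            thetas.append(fit.frailty_variance)
        assert np.mean(thetas) == pytest.approx(0.2, abs=0.05)


class TestValidationAndErrors:
    def test_no_events_rejected(self):
        data = pd.DataFrame({
            "cluster": [0, 0, 1, 1], "x": [0, 1, 0, 1],
            "y": [1.0, 2.0, 3.0, 4.0], "c": [1, 1, 1, 1],
        })
        with pytest.raises(FitError):
            fit_cox_marginal(data, ["x"])

    def test_constant_covariate_rejected(self, clustered_data):
        data = clustered_data.assign(x=1)
        with pytest.raises(FitError):
            fit_cox_marginal(data, ["x"])

    def test_unknown_model_name(self, clustered_data):
        with pytest.raises(ValueError):
            fit_cox(clustered_data, ["x"], model="weibull")

    def test_wald_pvalue_consistency(self, clustered_data):
        from scipy import stats

        fit = fit_cox_marginal(clustered_data, ["x"], robust=False)
        z = fit.coef[0] / fit.se[0]
        assert fit.pvalue[0] == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)
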