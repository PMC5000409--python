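"""Cohort generation: random effects, 10-year risk, refusal assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from cmrctsim.cohort import (
    CohortParams,
    RefusalSpec,
    assign_refusal,
    draw_random_effects,
    generate_cohort,
    realized_refusal_risk_correlation,
    ten_year_risk,
)


class TestRandomEffects:
    def test_degenerate_variances_give_zeros(self):
        params = CohortParams(J=10, K=4, sigma2_eps=0.0, sigma2_u=0.0)
        df = draw_random_effects(params, seed=1)
        assert np.all(df["eps"] == 0.0)
        assert np.all(df["u"] == 0.0)

    def test_same_seed_reproduces(self):
        params = CohortParams(J=20, K=5)
        a = draw_random_effects(params, seed=123)
        b = draw_random_effects(params, seed=123)
        pd.testing.assert_frame_equal(a, b)

    def test_cluster_members_share_u(self):
        params = CohortParams(J=30, K=8)
        df = draw_random_effects(params, seed=3)
        assert (df.groupby("cluster")["u"].nunique() == 1).all()
        assert df["u"].nunique() == 8

    def test_sample_variances_match_parameters(self):
        # N = 100,000 subjects: variances recovered within Monte-Carlo error
        params = CohortParams(J=100, K=1000)
        df = draw_random_effects(params, seed=5)
        assert df["eps"].var() == pytest.approx(0.6, rel=0.03)
        u_k = df.groupby("cluster")["u"].first()
        assert u_k.var() == pytest.approx(0.2, rel=0.15)

    def test_invalid_variance_rejected(self):
        with pytest.raises(ValueError):
            CohortParams(sigma2_eps=-0.1)


class TestTenYearRisk:
    def test_closed_form_at_zero(self):
        # 1 - exp(-(10/36)^1.2) with default shape/scale
        assert ten_year_risk(0.0) == pytest.approx(0.193458, abs=1e-6)

    def test_limits(self):
        assert ten_year_risk(-60.0) == pytest.approx(0.0, abs=1e-12)
        assert ten_year_risk(60.0) == pytest.approx(1.0, abs=1e-12)
        assert 0.0 < ten_year_risk(-60.0)  # strictly inside (0, 1)

    def test_monotone_in_linear_predictor(self):
        grid = np.linspace(-4, 4, 101)
        risks = ten_year_risk(grid)
        assert np.all(np.diff(risks) > 0)

    def test_agrees_with_numerical_hazard_integration(self):
        # integrating the individual hazard over [0, 10] must reproduce the
        # closed form: r = 1 - exp(-int_0^10 h(t) e^lp dt)
        gamma_c, lambda_c = 1.2, 36.0
        for lp in (-1.0, 0.0, 0.7):
            H, _ = quad(
                lambda t: gamma_c * t ** (gamma_c - 1) / lambda_c**gamma_c * np.exp(lp),
                0.0, 10.0,
            )
            assert ten_year_risk(lp, gamma_c, lambda_c) == pytest.approx(
                1.0 - np.exp(-H), abs=1e-6
            )

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            ten_year_risk(np.inf)


def _cohort_with_risks(n: int, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "cluster": np.zeros(n, dtype=int),
        "eps": np.zeros(n),
        "u": np.zeros(n),
        "risk10": rng.uniform(0.01, 0.9, n),
    })


class TestRefusalAssignment:
    def test_zero_tier_is_constant(self):
        cohort = _cohort_with_risks(50)
        out = assign_refusal(cohort, RefusalSpec(p=0.2, tier_p="zero"))
        assert np.all(out["p_refuse"] == 0.2)

    def test_three_subject_high_tier_grid(self):
        # p=0.2, (LL, UL) = (0, 0.4): ascending-risk probabilities {0, .2, .4}
        cohort = _cohort_with_risks(3, seed=1)
        out = assign_refusal(
            cohort, RefusalSpec(p=0.2, tier_p="high", sign_p="positive")
        )
        ordered = out.sort_values("risk10")["p_refuse"].to_numpy()
        assert ordered == pytest.approx([0.0, 0.2, 0.4])
        assert out["p_refuse"].mean() == pytest.approx(0.2, abs=1e-12)

    def test_negative_sign_reverses_grid(self):
        cohort = _cohort_with_risks(3, seed=1)
        out = assign_refusal(
            cohort, RefusalSpec(p=0.2, tier_p="high", sign_p="negative")
        )
        ordered = out.sort_values("risk10")["p_refuse"].to_numpy()
        assert ordered == pytest.approx([0.4, 0.2, 0.0])

    def test_zero_mean_gives_all_zero(self):
        cohort = _cohort_with_risks(10)
        out = assign_refusal(cohort, RefusalSpec(p=0.0, tier_p="high"))
        assert np.all(out["p_refuse"] == 0.0)

    @settings(max_examples=40, deadline=None)
    @given(
        p=st.floats(0.01, 0.5),
        tier=st.sampled_from(["zero", "low", "medium", "high"]),
        sign=st.sampled_from(["positive", "negative"]),
        n=st.integers(2, 400),
    )
    def test_mean_refusal_is_exact(self, p, tier, sign, n):
        cohort = _cohort_with_risks(n, seed=7)
        out = assign_refusal(
            cohort, RefusalSpec(p=p, tier_p=tier, sign_p=sign), seed=11
        )
        assert abs(out["p_refuse"].mean() - p) < 1e-9

    def test_permutation_equivariance(self):
        # shuffling subject order must not change the (risk, refusal) pairing
        cohort = _cohort_with_risks(200, seed=3)
        spec = RefusalSpec(p=0.3, tier_p="medium", sign_p="positive")
        out1 = assign_refusal(cohort, spec, seed=0)
        shuffled = cohort.sample(frac=1.0, random_state=9).reset_index(drop=True)
        out2 = assign_refusal(shuffled, spec, seed=0)
        pairing1 = out1.sort_values("risk10")["p_refuse"].to_numpy()
        pairing2 = out2.sort_values("risk10")["p_refuse"].to_numpy()
        assert pairing1 == pytest.approx(pairing2)

    def test_q_assigned_on_same_ordering(self):
        cohort = _cohort_with_risks(100, seed=4)
        spec = RefusalSpec(
            p=0.2, q=0.1, tier_p="high", tier_q="high",
            sign_p="positive", sign_q="negative",
        )
        out = assign_refusal(cohort, spec)
        # opposite signs on the same ordering: perfectly anti-correlated
        assert np.corrcoef(out["p_refuse"], out["q_refuse"])[0, 1] == pytest.approx(-1.0)

    def test_high_tier_limits_validated(self):
        with pytest.raises(ValueError):
            RefusalSpec(p=0.6, tier_p="high")  # UL = 1.2 > 1


class TestRealizedCorrelation:
    def test_zero_tier_reports_zero(self):
        cohort = _cohort_with_risks(50)
        out = assign_refusal(cohort, RefusalSpec(p=0.2, tier_p="zero"))
        assert realized_refusal_risk_correlation(out) == 0.0

    def test_signs(self):
        cohort = _cohort_with_risks(500, seed=5)
        pos = assign_refusal(cohort, RefusalSpec(p=0.2, tier_p="high", sign_p="positive"))
        neg = assign_refusal(cohort, RefusalSpec(p=0.2, tier_p="high", sign_p="negative"))
        assert realized_refusal_risk_correlation(pos) > 0.5
        assert realized_refusal_risk_correlation(neg) < -0.5

    def test_wider_tier_gives_stronger_correlation(self):
        cohort = _cohort_with_risks(500, seed=6)
        high = assign_refusal(cohort, RefusalSpec(p=0.2, tier_p="high", sign_p="positive"))
        low = assign_refusal(cohort, RefusalSpec(p=0.2, tier_p="low", sign_p="positive"))
        assert abs(realized_refusal_risk_correlation(high)) >= abs(
            realized_refusal_risk_correlation(low)
        ) - 1e-12


def test_generate_cohort_is_complete_and_reproducible():
    params = CohortParams(J=25, K=6)
    spec = RefusalSpec(p=0.2, tier_p="medium", sign_p="negative")
    a = generate_cohort(params, spec, seed=99)
    b = generate_cohort(params, spec, seed=99)
    pd.testing.assert_frame_equal(a, b)
    assert set(a.columns) >= {"cluster", "eps", "u", "risk10", "p_refuse", "q_refuse"}
    assert ((a["risk10"] > 0) & (a["risk10"] < 1)).all()
    assert a["p_refuse"].mean() == pytest.approx(0.2, abs=1e-9)
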