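"""Latent cohort structure for cluster cmRCT simulations.

A cohort-multiple randomised controlled trial (cmRCT) draws its intervention
and control groups from a standing cohort — here a population at elevated
cardiovascular (CVD) risk, clustered by primary-care practice.  This module
generates the latent quantities every simulated trial is built on:

* individual and cluster random effects ``eps`` and ``u`` (normal, acting
  multiplicatively on the hazard scale, i.e. shared frailties),
* each subject's counterfactual 10-year CVD risk under usual care, and
* patient and clinician refusal probabilities assigned rank-linearly over
  the risk ordering, which is how the correlation between refusal and risk
  is controlled.

Refusal happens post-randomisation in a cmRCT, so these probabilities are
properties of the cohort, fixed before any treatment is offered.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "CohortParams",
    "RefusalSpec",
    "TIER_LIMITS",
    "draw_random_effects",
    "ten_year_risk",
    "assign_refusal",
    "realized_refusal_risk_correlation",
    "generate_cohort",
]

Tier = Literal["zero", "low", "medium", "high"]
Sign = Literal["positive", "negative"]

#: (lower, upper) refusal-probability limits as multiples of the mean level.
TIER_LIMITS: dict[str, tuple[float, float]] = {
    "zero": (1.0, 1.0),
    "low": (2.0 / 3.0, 4.0 / 3.0),
    "medium": (1.0 / 3.0, 5.0 / 3.0),
    "high": (0.0, 2.0),
}


@dataclass(frozen=True)
class CohortParams:
    """Generative constants for the cohort and its survival processes.

    Defaults describe a UK primary-care CVD-prevention setting: clusters are
    GP practices of ``J = 620`` eligible patients; times to CVD event and to
    death are Weibull with shape 1.2 and scales 36 and 55 years; the
    intervention multiplies the CVD hazard by ``exp(beta)`` with
    ``beta = -0.32``; follow-up is administratively censored at 3 years.

    Parameters
    ----------
    J : subjects per cluster.
    K : number of clusters in the trial.
    gamma_c, lambda_c : Weibull shape / scale (years) for the CVD event time.
    gamma_m, lambda_m : Weibull shape / scale (years) for the mortality time.
    sigma2_eps : variance of the individual random effect on the log-hazard.
    sigma2_u : variance of the cluster random effect on the log-hazard.
    beta : log hazard ratio of the intervention on the CVD hazard.
    T_max : follow-up horizon in years.
    icc_label : metadata tag for the intra-cluster-correlation setting the
        variance pair stands for ("0.025" for (0.6, 0.2), "0.05" for
        (0.57, 0.27)); carried through to outputs, never used in formulas.
    """

    J: int = 620
    K: int = 25
    gamma_c: float = 1.2
    lambda_c: float = 36.0
    gamma_m: float = 1.2
    lambda_m: float = 55.0
    sigma2_eps: float = 0.6
    sigma2_u: float = 0.2
    beta: float = -0.32
    T_max: float = 3.0
    icc_label: str = "0.025"

    def __post_init__(self) -> None:
        if self.J < 2 or self.K < 2:
            raise ValueError("J and K must both be at least 2")
        for name in ("gamma_c", "lambda_c", "gamma_m", "lambda_m", "T_max"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sigma2_eps", "sigma2_u"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def N(self) -> int:
        return self.J * self.K

    def with_(self, **kwargs) -> "CohortParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RefusalSpec:
    """Mean refusal levels and how strongly they track individual risk.

    ``p`` is the mean probability a patient refuses an offered intervention,
    ``q`` the mean probability the clinician declines to offer it.  The tier
    picks the width of the rank-linear grid of individual probabilities,
    (LL, UL) in {(p, p), (2p/3, 4p/3), (p/3, 5p/3), (0, 2p)} for
    zero/low/medium/high, and the sign picks whether the grid runs up
    (positive: highest-risk patients refuse most) or down the risk ordering.
    """

    p: float = 0.0
    q: float = 0.0
    tier_p: Tier = "zero"
    tier_q: Tier = "zero"
    sign_p: Sign = "negative"
    sign_q: Sign = "negative"

    def __post_init__(self) -> None:
        for mean, tier, label in ((self.p, self.tier_p, "p"), (self.q, self.tier_q, "q")):
            if not 0.0 <= mean <= 1.0:
                raise ValueError(f"mean refusal {label} must be in [0, 1]")
            lo, hi = self.limits(mean, tier)
            if lo < 0.0 or hi > 1.0:
                raise ValueError(
                    f"tier '{tier}' at mean {label}={mean} gives limits ({lo}, {hi}) outside [0, 1]"
                )

    @staticmethod
    def limits(mean: float, tier: str) -> tuple[float, float]:
        try:
            lo_m, hi_m = TIER_LIMITS[tier]
        except KeyError:
            raise ValueError(f"unknown tier {tier!r}") from None
        return lo_m * mean, hi_m * mean


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_random_effects(params: CohortParams, seed) -> pd.DataFrame:
    """Draw individual and cluster random effects for a fresh cohort.

    Returns a frame with one row per subject and columns ``cluster``
    (0..K-1), ``eps`` ~ N(0, sigma2_eps) i.i.d., and ``u`` ~ N(0, sigma2_u)
    drawn once per cluster and shared by its members.
    """
    rng = _as_rng(seed)
    cluster = np.repeat(np.arange(params.K), params.J)
    eps = rng.normal(0.0, np.sqrt(params.sigma2_eps), params.N)
    u_k = rng.normal(0.0, np.sqrt(params.sigma2_u), params.K)
    return pd.DataFrame({"cluster": cluster, "eps": eps, "u": u_k[cluster]})


def ten_year_risk(eps_plus_u, gamma_c: float = 1.2, lambda_c: float = 36.0):
    """Counterfactual 10-year event probability under usual care.

    The individual hazard is the Weibull baseline ``gamma*t^(gamma-1)/lambda^gamma``
    times ``exp(eps + u)``, so conditional on the random effects

        r = 1 - exp(-(10 / lambda_c)**gamma_c * exp(eps + u)).

    Strictly increasing in ``eps_plus_u`` and strictly inside (0, 1).
    """
    if not (gamma_c > 0 and lambda_c > 0):
        raise ValueError("Weibull shape and scale must be positive")
    x = np.asarray(eps_plus_u, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("eps_plus_u must be finite")
    risk = -np.expm1(-((10.0 / lambda_c) ** gamma_c) * np.exp(x))
    return risk if risk.ndim else float(risk)


def _rank_linear(n: int, lo: float, hi: float, ranks: np.ndarray, ascending: bool) -> np.ndarray:
    """Probabilities on an even grid from lo to hi along the given risk ranks."""
    if n < 2:
        raise ValueError("rank-linear assignment needs at least 2 subjects")
    grid = lo + (hi - lo) * np.arange(n) / (n - 1)
    if not ascending:
        grid = grid[::-1]
    return grid[ranks]  # subject with rank r gets the r-th grid value


def assign_refusal(cohort: pd.DataFrame, spec: RefusalSpec, seed=0) -> pd.DataFrame:
    """Attach patient and clinician refusal probabilities to a cohort.

    Subjects are ordered by ``risk10`` over the whole cohort and probabilities
    are laid out linearly between the tier limits along that single ordering,
    so the realised mean equals the specified mean and the refusal-risk
    correlation is set by the tier width and sign.  Patient and clinician
    probabilities use the same risk ordering (each with its own tier/sign).
    Risk ties — measure-zero with continuous effects — are broken by a seeded
    uniform jitter so the assignment is deterministic given the seed.
    """
    rng = _as_rng(seed)
    risk = cohort["risk10"].to_numpy()
    n = len(risk)
    out = cohort.copy()
    # ranks[i] = position of subject i in ascending-risk order, ties randomised
    order = np.lexsort((rng.random(n), risk))
    ranks = np.empty(n, dtype=np.intp)
    ranks[order] = np.arange(n)

    for mean, tier, sign, col in (
        (spec.p, spec.tier_p, spec.sign_p, "p_refuse"),
        (spec.q, spec.tier_q, spec.sign_q, "q_refuse"),
    ):
        lo, hi = RefusalSpec.limits(mean, tier)
        if tier == "zero" or mean == 0.0:
            out[col] = np.full(n, mean)
        else:
            out[col] = _rank_linear(n, lo, hi, ranks, ascending=(sign == "positive"))
    return out


def realized_refusal_risk_correlation(cohort: pd.DataFrame, which: str = "patient") -> float:
    """Pearson correlation between assigned refusal probability and risk.

    Diagnostic only — the generator controls the correlation through the tier,
    never through this number.  A constant refusal vector (zero tier) has no
    defined correlation and is reported as 0 by convention.
    """
    col = {"patient": "p_refuse", "clinician": "q_refuse"}[which]
    p = cohort[col].to_numpy()
    r = cohort["risk10"].to_numpy()
    if np.ptp(p) == 0.0 or np.ptp(r) == 0.0:
        return 0.0
    return float(np.corrcoef(p, r)[0, 1])


def generate_cohort(params: CohortParams, spec: RefusalSpec, seed) -> pd.DataFrame:
    """Random effects, risks and refusal probabilities in one call.

    Returns the full cohort frame with columns ``cluster, eps, u, risk10,
    p_refuse, q_refuse``; reproducible given the seed.
    """
    rng = _as_rng(seed)
    cohort = draw_random_effects(params, rng)
    cohort["risk10"] = ten_year_risk(
        cohort["eps"].to_numpy() + cohort["u"].to_numpy(), params.gamma_c, params.lambda_c
    )
    return assign_refusal(cohort, spec, rng)
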