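"""Simulation-based sample-size determination for a cluster cmRCT.

Closed-form sample-size formulas are not available for informatively
censored, clustered survival data, so the required size is found by
simulation: for a candidate number of clusters K (N = K * J subjects,
allocated 4:1), trials are simulated and analysed with ITT, and the
smallest K whose empirical power reaches the target is returned.

Two recruitment methods are supported:

* method 1 ignores refusal (``assumed_refusal = 0``);
* method 2 inflates the sample size for an assumed *non-informative*
  refusal rate — every subject refuses independently with the same
  probability, uncorrelated with risk (the zero-correlation tier).

The search uses a normal-approximation pilot to bracket K (empirical SE of
the ITT estimate scales as 1/sqrt(K)), then walks the power curve at
single-cluster granularity with a fixed common random-number stream across
candidates so that the minimality decision is not dominated by Monte-Carlo
noise between candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortParams, RefusalSpec
from .experiment import Scenario, run_scenario

__all__ = ["SampleSizeResult", "power_at", "find_sample_size", "update_sample_size"]


@dataclass
class SampleSizeResult:
    K_star: int
    N_star: int
    achieved_power: float
    reps_used: int
    method: int  # recruitment method: 1 ignores refusal, 2 factors it in
    assumed_refusal: float
    target_power: float
    alpha: float
    model: str
    power_curve: dict[int, float] = field(default_factory=dict)


def _scenario(params: CohortParams, K: int, refusal: float, reps: int,
              base_seed: int, model: str, alpha: float) -> Scenario:
    return Scenario(
        params=params.with_(K=K),
        refusal=RefusalSpec(p=refusal, tier_p="zero"),
        model=model, methods=("itt",), reps=reps, base_seed=base_seed,
        alpha=alpha, label=f"samplesize_K{K}",
    )


def power_at(params: CohortParams, K: int, refusal: float, reps: int,
             base_seed: int = 0, model: str = "lognormal",
             alpha: float = 0.05) -> tuple[float, float, float]:
    """Empirical ITT power, mean estimate and empirical SE at K clusters."""
    res = run_scenario(_scenario(params, K, refusal, reps, base_seed, model, alpha))
    s = res.summaries["itt"]
    return s.power, s.mean_beta, s.emp_se


def find_sample_size(
    params: CohortParams,
    assumed_refusal: float = 0.0,
    alpha: float = 0.05,
    target_power: float = 0.8,
    reps: int = 200,
    model: str = "lognormal",
    base_seed: int = 0,
    K_max: int = 1000,
    pilot_K: int = 40,
    pilot_reps: int = 60,
) -> SampleSizeResult:
    """Smallest K (N a multiple of J) whose empirical ITT power meets target.

    A pilot at ``pilot_K`` clusters estimates the attenuated effect and its
    empirical SE; the normal approximation
    ``power = Phi(|beta_att| / se - z_{1-alpha/2})`` with ``se ~ 1/sqrt(K)``
    brackets the answer, which is then confirmed by walking candidate K
    down/up with the shared random-number stream until the smallest K with
    ``power >= target_power`` is found.
    """
    if not 0.0 <= assumed_refusal < 1.0:
        raise ValueError("assumed_refusal must be in [0, 1)")
    from scipy import stats

    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(target_power)
    _, beta_att, se_pilot = power_at(
        params, pilot_K, assumed_refusal, pilot_reps, base_seed, model, alpha
    )
    se_target = abs(beta_att) / (z_a + z_b)
    K_guess = int(np.ceil(pilot_K * (se_pilot / se_target) ** 2))
    K_guess = max(5, min(K_guess, K_max))

    curve: dict[int, float] = {}

    def power(K: int) -> float:
        if K not in curve:
            curve[K] = power_at(params, K, assumed_refusal, reps, base_seed,
                                model, alpha)[0]
        return curve[K]

    # bracket [K_lo, K_hi] with power < target at K_lo and >= target at K_hi,
    # then bisect to single-cluster granularity; the common random numbers
    # make power(K) a deterministic (and near-monotone) function of K
    K_hi = K_guess
    while power(K_hi) < target_power:
        K_hi = min(int(np.ceil(K_hi * 1.3)) + 1, K_max)
        if K_hi == K_max and power(K_hi) < target_power:
            raise RuntimeError(
                f"target power {target_power} unreachable within K <= {K_max}; "
                f"power curve so far: {dict(sorted(curve.items()))}"
            )
    K_lo = max(2, int(K_hi * 0.8) - 1)
    while power(K_lo) >= target_power:
        if K_lo <= 2:
            break
        K_lo = max(2, int(K_lo * 0.8) - 1)
    if power(K_lo) >= target_power:
        K = K_lo  # even the smallest admissible design is powered
    else:
        while K_hi - K_lo > 1:
            mid = (K_hi + K_lo) // 2
            if power(mid) >= target_power:
                K_hi = mid
            else:
                K_lo = mid
        K = K_hi
    method = 1 if assumed_refusal == 0.0 else 2
    return SampleSizeResult(
        K_star=K, N_star=K * params.J, achieved_power=curve[K], reps_used=reps,
        method=method, assumed_refusal=assumed_refusal,
        target_power=target_power, alpha=alpha, model=model,
        power_curve=dict(sorted(curve.items())),
    )


def update_sample_size(current: SampleSizeResult, observed_refusal: float,
                       params: CohortParams, **kwargs) -> SampleSizeResult:
    """Revise the required size once the realised refusal rate is observed.

    Intended for interim looks: re-runs the search at the observed rate with
    the same design constants; the caller can compare ``K_star`` values to
    decide whether recruitment needs extending or can stop early.
    """
    kwargs.setdefault("alpha", current.alpha)
    kwargs.setdefault("target_power", current.target_power)
    kwargs.setdefault("reps", current.reps_used)
    kwargs.setdefault("model", current.model)
    return find_sample_size(params, assumed_refusal=observed_refusal, **kwargs)
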