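"""Turn a cohort into one simulated cluster cmRCT.

The trial pipeline is: randomise whole clusters 4:1 control:intervention,
resolve treatment uptake (a patient in an intervention cluster receives the
intervention only if neither they nor their clinician refuses), generate
Weibull event and mortality times from hazards carrying the shared random
effects, and apply administrative censoring at ``T_max``.

Column conventions of the resulting trial frame (one row per subject):

== ===========================================================
z  allocated treatment, constant within cluster (0/1)
x  treatment received (0/1, always 0 when z = 0)
y  observed time in years, ``min(t_c, t_m, T_max)``
c  censoring indicator, 1 when the CVD event was *not* observed
== ===========================================================

The latent times ``t_c`` (CVD) and ``t_m`` (death) are kept for diagnostics
but must never be given to an estimator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortParams, _as_rng

__all__ = [
    "randomize_clusters",
    "treatment_received",
    "sample_event_time",
    "apply_censoring",
    "simulate_trial",
    "LATENT_COLUMNS",
]

LATENT_COLUMNS = ("eps", "u", "risk10", "p_refuse", "q_refuse", "t_c", "t_m")


def randomize_clusters(K: int, seed, ratio_control_to_intervention: int = 4) -> np.ndarray:
    """Allocate clusters to control (0) or intervention (1).

    Exactly ``round(K / (ratio+1))`` clusters, but at least one, are drawn
    uniformly without replacement for the intervention arm; with the default
    4:1 ratio and K a multiple of 5 this is exact.
    """
    if K < 2:
        raise ValueError("need at least 2 clusters to randomise")
    rng = _as_rng(seed)
    n_int = max(1, round(K / (ratio_control_to_intervention + 1)))
    z = np.zeros(K, dtype=np.int64)
    z[rng.choice(K, size=n_int, replace=False)] = 1
    return z


def treatment_received(z, p_ik, q_ik, seed) -> np.ndarray:
    """Resolve uptake: x = min(Bern(1-p), Bern(1-q)) when allocated, else 0.

    Patient and clinician refusals are two independent Bernoulli draws, so an
    allocated subject receives the intervention with probability
    ``(1 - p_ik) * (1 - q_ik)``.  Control subjects never receive it.
    """
    rng = _as_rng(seed)
    z = np.asarray(z)
    p = np.asarray(p_ik, dtype=float)
    q = np.asarray(q_ik, dtype=float)
    accept_patient = rng.random(z.shape) >= p
    accept_clinician = rng.random(z.shape) >= q
    return (z == 1) & accept_patient & accept_clinician


def sample_event_time(shape: float, scale: float, linear_predictor, seed, size=None) -> np.ndarray:
    """Inverse-CDF draw from a Weibull proportional-hazards model.

    The hazard is ``shape * t**(shape-1) / scale**shape * exp(linear_predictor)``,
    i.e. Weibull with survivor function ``exp(-(t/lam)**shape)`` where
    ``lam = scale * exp(-linear_predictor / shape)``.  One uniform draw maps
    to one time, so larger linear predictors give strictly smaller times at
    a fixed draw.
    """
    if not (shape > 0 and scale > 0):
        raise ValueError("Weibull shape and scale must be positive")
    rng = _as_rng(seed)
    lp = np.asarray(linear_predictor, dtype=float)
    if size is None:
        size = lp.shape
    u = rng.random(size)
    return scale * np.exp(-lp / shape) * (-np.log(u)) ** (1.0 / shape)


def apply_censoring(t_c, t_m, T_max: float):
    """Observed time and censoring indicator.

    ``y = min(t_c, t_m, T_max)``; ``c = 1`` exactly when the CVD event is
    pre-empted by death or by the end of follow-up,
    ``c = I(t_c >= min(t_m, T_max))``.
    """
    t_c = np.asarray(t_c, dtype=float)
    t_m = np.asarray(t_m, dtype=float)
    y = np.minimum(np.minimum(t_c, t_m), T_max)
    c = (t_c >= np.minimum(t_m, T_max)).astype(np.int64)
    return y, c


def simulate_trial(cohort: pd.DataFrame, params: CohortParams, seed) -> pd.DataFrame:
    """Run one complete trial on a generated cohort.

    The CVD hazard carries ``beta*x + eps + u``; the mortality hazard only
    ``eps + u`` (death is never affected by the intervention), which is what
    makes censoring by death informative.  Returns the cohort frame extended
    with ``z, x, t_c, t_m, y, c``.
    """
    rng = _as_rng(seed)
    K = int(cohort["cluster"].max()) + 1
    z_cluster = randomize_clusters(K, rng)
    out = cohort.copy()
    cluster = out["cluster"].to_numpy()
    z = z_cluster[cluster]
    x = treatment_received(z, out["p_refuse"].to_numpy(), out["q_refuse"].to_numpy(), rng)

    re = out["eps"].to_numpy() + out["u"].to_numpy()
    t_c = sample_event_time(params.gamma_c, params.lambda_c, params.beta * x + re, rng)
    t_m = sample_event_time(params.gamma_m, params.lambda_m, re, rng)
    y, c = apply_censoring(t_c, t_m, params.T_max)

    out["z"] = z
    out["x"] = x.astype(np.int64)
    out["t_c"] = t_c
    out["t_m"] = t_m
    out["y"] = y
    out["c"] = c
    return out


def censoring_diagnostics(trial: pd.DataFrame) -> dict[str, float]:
    """Realised censoring composition of one simulated trial.

    Fractions of subjects whose CVD event was observed, pre-empted by death
    within follow-up, or administratively censored at ``T_max``.  Reported
    as a diagnostic because the relative size of death censoring is a
    calibration property of the mortality process, not an enforced target.
    """
    event = (trial["c"] == 0).to_numpy()
    death = ((trial["c"] == 1) & (trial["t_m"] <= trial["y"])).to_numpy()
    return {
        "event_fraction": float(event.mean()),
        "death_censored_fraction": float(death.mean()),
        "administrative_fraction": float(1.0 - event.mean() - death.mean()),
        "death_to_event_ratio": float(death.sum() / max(event.sum(), 1)),
    }


def export_trial(trial: pd.DataFrame, path, include_latent: bool = False) -> None:
    """Write the minimal survival table (cluster, z, x, y, c) as CSV."""
    cols = ["cluster", "z", "x", "y", "c"]
    if include_latent:
        cols += [c for c in LATENT_COLUMNS if c in trial.columns]
    trial[cols].to_csv(path, index=False)
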