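"""The four analysis methods for a cluster cmRCT with refusal.

* ITT — Cox fit on allocation ``z``; estimates the effect of *offering* the
  intervention and is diluted towards the null by refusers.
* PP — per protocol: intervention-cluster refusers are dropped and the fit
  uses treatment received ``x``; prone to selection bias when refusal is
  correlated with risk.
* 2SPS — two-stage predictor substitution: a linear first stage of ``x`` on
  ``z`` (the randomised allocation is the instrument), then a Cox fit on
  the fitted values.
* 2SRI — two-stage residual inclusion: the Cox fit uses both ``x`` and the
  first-stage residual; the residual proxies the unobserved acceptance
  propensity, which is what absorbs risk-correlated refusal.

Second-stage model-based standard errors understate the uncertainty of the
two-stage procedures, so a cluster bootstrap (resampling whole clusters,
the randomisation unit) is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import _as_rng
from .cox import CoxFit, FitError, fit_cox

__all__ = [
    "MethodEstimate",
    "estimate_itt",
    "estimate_pp",
    "first_stage",
    "estimate_2sps",
    "estimate_2sri",
    "bootstrap_se",
    "estimate",
    "METHODS",
]

#: residual variance below which the 2SRI residual column is collinear noise
_RESID_VAR_TOL = 1e-12


@dataclass
class MethodEstimate:
    """One method's treatment-effect estimate on one simulated trial."""

    method: str
    coef: float
    se_naive: float
    pvalue: float
    n_used: int
    converged: bool
    fit: CoxFit
    se_bootstrap: float | None = None
    note: str = ""


def _wrap(method: str, fit: CoxFit, name: str, n_used: int, note: str = "") -> MethodEstimate:
    coef, se, p = fit[name]
    return MethodEstimate(
        method=method, coef=coef, se_naive=se, pvalue=p, n_used=n_used,
        converged=fit.converged, fit=fit, note=note,
    )


def estimate_itt(trial: pd.DataFrame, model: str = "lognormal", **kwargs) -> MethodEstimate:
    """Intention to treat: analyse by randomised allocation."""
    fit = fit_cox(trial, ["z"], model=model, **kwargs)
    return _wrap("ITT", fit, "z", len(trial))


def estimate_pp(trial: pd.DataFrame, model: str = "lognormal", **kwargs) -> MethodEstimate:
    """Per protocol: drop intervention-cluster refusers, analyse by receipt.

    Controls trivially follow their allocation and are all retained.
    """
    keep = (trial["z"].to_numpy() == 0) | (trial["x"].to_numpy() == 1)
    sub = trial.loc[keep]
    fit = fit_cox(sub, ["x"], model=model, **kwargs)
    return _wrap("PP", fit, "x", len(sub))


def first_stage(trial: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Linear first stage of treatment received on allocation.

    Least squares of binary ``x`` on binary ``z`` saturates the group means:
    fitted uptake is 0 for controls and the observed acceptance rate in the
    intervention arm.  Returns (fitted values, residuals) per subject.
    """
    z = trial["z"].to_numpy()
    x = trial["x"].to_numpy()
    if not (z == 1).any():
        raise FitError("instrument has no variation: no intervention clusters")
    xhat = np.where(z == 1, x[z == 1].mean(), x[z == 0].mean() if (z == 0).any() else 0.0)
    return xhat, x - xhat


def estimate_2sps(trial: pd.DataFrame, model: str = "lognormal", **kwargs) -> MethodEstimate:
    """Two-stage predictor substitution: Cox on the first-stage fitted values."""
    xhat, _ = first_stage(trial)
    data = trial.assign(xhat=xhat)
    fit = fit_cox(data, ["xhat"], model=model, **kwargs)
    return _wrap("2SPS", fit, "xhat", len(trial))


def estimate_2sri(trial: pd.DataFrame, model: str = "lognormal", **kwargs) -> MethodEstimate:
    """Two-stage residual inclusion: Cox on treatment received plus residual.

    With full compliance the residual is identically zero; it is then
    dropped (noted on the estimate) and the fit reduces to the ITT fit.
    """
    xhat, resid = first_stage(trial)
    if resid.var() < _RESID_VAR_TOL:
        fit = fit_cox(trial, ["x"], model=model, **kwargs)
        return _wrap("2SRI", fit, "x", len(trial),
                     note="constant first-stage residual dropped")
    data = trial.assign(resid=resid)
    fit = fit_cox(data, ["x", "resid"], model=model, **kwargs)
    return _wrap("2SRI", fit, "x", len(trial))


_ESTIMATORS = {
    "itt": estimate_itt,
    "pp": estimate_pp,
    "2sps": estimate_2sps,
    "2sri": estimate_2sri,
}

METHODS = tuple(_ESTIMATORS)


def estimate(trial: pd.DataFrame, method: str, model: str = "lognormal",
             **kwargs) -> MethodEstimate:
    """Run one analysis method by name ('itt', 'pp', '2sps', '2sri')."""
    try:
        est = _ESTIMATORS[method.lower()]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}") from None
    return est(trial, model=model, **kwargs)


def bootstrap_se(trial: pd.DataFrame, estimator: str, B: int = 200, seed=0,
                 model: str = "lognormal") -> float:
    """Cluster-bootstrap standard error of a two-stage estimator.

    Clusters are resampled with replacement (preserving the randomisation
    unit) and both stages are re-run on each resample; the SE is the SD of
    the B coefficient estimates.  Resamples without events in both arms are
    skipped.
    """
    if B < 50:
        raise ValueError("use at least 50 bootstrap resamples")
    rng = _as_rng(seed)
    clusters = trial["cluster"].unique()
    by_cluster = {k: v for k, v in trial.groupby("cluster")}
    coefs = []
    for _ in range(B):
        picked = rng.choice(clusters, size=len(clusters), replace=True)
        parts = []
        for new_id, k in enumerate(picked):
            part = by_cluster[k].copy()
            part["cluster"] = new_id  # resampled copies are distinct clusters
            parts.append(part)
        resample = pd.concat(parts, ignore_index=True)
        try:
            coefs.append(estimate(resample, estimator, model=model).coef)
        except FitError:
            continue
    if len(coefs) < 2:
        raise FitError("too few successful bootstrap resamples")
    return float(np.std(coefs, ddof=1))
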