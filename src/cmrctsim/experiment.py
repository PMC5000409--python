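"""Replication engine: repeat simulated trials and summarise bias and power.

One *scenario* fixes the cohort parameters, the refusal specification, the
Cox-model clustering treatment and the analysis methods.  For each of
``reps`` replicates a fresh cohort is generated, one trial is simulated and
every requested method is run; the per-method summaries are

* the mean estimate over converged replicates,
* the percentage bias ``100 (mean - beta) / beta`` with a normal-theory CI
  built from the standard error of the mean,
* the empirical SE (SD of the replicate estimates), and
* the power, the fraction of replicate p-values below alpha.

Replicates on which a fit fails or does not converge are excluded from the
summaries with a recorded count; a scenario with more than 20 % failed
replicates is flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortParams, RefusalSpec, generate_cohort
from .cox import FitError
from .estimators import estimate
from .trial import simulate_trial

__all__ = [
    "Scenario",
    "MethodSummary",
    "ScenarioResult",
    "run_replicate",
    "run_scenario",
    "summarize",
    "run_grid",
]

MAX_FAILED_FRACTION = 0.2


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation study."""

    params: CohortParams
    refusal: RefusalSpec
    model: str = "lognormal"
    methods: tuple[str, ...] = ("itt", "pp", "2sps", "2sri")
    reps: int = 1000
    base_seed: int = 0
    recruitment_method: int = 1
    alpha: float = 0.05
    label: str = ""

    def __post_init__(self) -> None:
        if self.reps < 2:
            raise ValueError("need at least 2 replicates")
        if self.recruitment_method not in (1, 2):
            raise ValueError("recruitment_method must be 1 or 2")


@dataclass
class MethodSummary:
    method: str
    mean_beta: float
    pct_bias: float
    pct_bias_ci: tuple[float, float]
    emp_se: float
    se_of_mean: float
    power: float
    n_converged: int
    n_failed: int


@dataclass
class ScenarioResult:
    scenario: Scenario
    summaries: dict[str, MethodSummary]
    estimates: pd.DataFrame  # long format: rep, method, coef, pvalue, converged
    valid: bool

    def to_rows(self) -> pd.DataFrame:
        s, rows = self.scenario, []
        for m in self.summaries.values():
            rows.append({
                "label": s.label, "model": s.model, "K": s.params.K, "J": s.params.J,
                "beta": s.params.beta, "p": s.refusal.p, "q": s.refusal.q,
                "tier_p": s.refusal.tier_p, "sign_p": s.refusal.sign_p,
                "tier_q": s.refusal.tier_q, "sign_q": s.refusal.sign_q,
                "recruitment_method": s.recruitment_method, "reps": s.reps,
                "method": m.method, "mean_beta": m.mean_beta,
                "pct_bias": m.pct_bias, "pct_bias_lo": m.pct_bias_ci[0],
                "pct_bias_hi": m.pct_bias_ci[1], "emp_se": m.emp_se,
                "se_of_mean": m.se_of_mean, "power": m.power,
                "n_converged": m.n_converged, "n_failed": m.n_failed,
                "valid": self.valid,
            })
        return pd.DataFrame(rows)


def replicate_seeds(base_seed: int, reps: int) -> list[np.random.SeedSequence]:
    """Independent, reproducible per-replicate seed streams."""
    return np.random.SeedSequence(base_seed).spawn(reps)


def run_replicate(scenario: Scenario, seed) -> list[dict]:
    """Simulate one trial and run every requested method on it."""
    rng = np.random.default_rng(seed)
    cohort = generate_cohort(scenario.params, scenario.refusal, rng)
    trial = simulate_trial(cohort, scenario.params, rng)
    rows = []
    for method in scenario.methods:
        try:
            est = estimate(trial, method, model=scenario.model)
            rows.append({
                "method": method, "coef": est.coef, "pvalue": est.pvalue,
                "converged": bool(est.converged),
            })
        except FitError:
            rows.append({"method": method, "coef": np.nan, "pvalue": np.nan,
                         "converged": False})
    return rows


def summarize(coefs: Sequence[float], pvalues: Sequence[float], beta_true: float,
              alpha: float = 0.05, method: str = "", n_failed: int = 0) -> MethodSummary:
    """Bias/power summaries over converged replicate estimates.

    ``pct_bias = 100 (mean - beta) / beta``; the CI applies the same map to
    ``mean ± 1.96 se_of_mean`` with ``se_of_mean = sd / sqrt(n)``.
    """
    coefs = np.asarray(coefs, dtype=float)
    pvalues = np.asarray(pvalues, dtype=float)
    if len(coefs) < 2:
        raise ValueError("need at least 2 converged replicates to summarise")
    mean = float(coefs.mean())
    emp_se = float(coefs.std(ddof=1))
    se_mean = emp_se / np.sqrt(len(coefs))
    pct = 100.0 * (mean - beta_true) / beta_true
    lo = 100.0 * ((mean - 1.96 * se_mean) - beta_true) / beta_true
    hi = 100.0 * ((mean + 1.96 * se_mean) - beta_true) / beta_true
    ci = (min(lo, hi), max(lo, hi))
    power = float((pvalues < alpha).mean())
    return MethodSummary(
        method=method, mean_beta=mean, pct_bias=pct, pct_bias_ci=ci,
        emp_se=emp_se, se_of_mean=float(se_mean), power=power,
        n_converged=len(coefs), n_failed=n_failed,
    )


def run_scenario(scenario: Scenario, progress: bool = False) -> ScenarioResult:
    """Run all replicates of a scenario and summarise each method."""
    records = []
    for j, ss in enumerate(replicate_seeds(scenario.base_seed, scenario.reps)):
        for row in run_replicate(scenario, ss):
            row["rep"] = j
            records.append(row)
        if progress and (j + 1) % 50 == 0:
            print(f"  [{scenario.label or 'scenario'}] replicate {j + 1}/{scenario.reps}",
                  flush=True)
    est = pd.DataFrame(records)
    summaries: dict[str, MethodSummary] = {}
    valid = True
    for method in scenario.methods:
        sub = est[est["method"] == method]
        ok = sub[sub["converged"] & sub["coef"].notna()]
        n_failed = len(sub) - len(ok)
        if n_failed > MAX_FAILED_FRACTION * len(sub):
            valid = False
        summaries[method] = summarize(
            ok["coef"], ok["pvalue"], scenario.params.beta,
            alpha=scenario.alpha, method=method, n_failed=n_failed,
        )
    return ScenarioResult(scenario=scenario, summaries=summaries, estimates=est,
                          valid=valid)


def run_grid(scenarios: Iterable[Scenario], out: str | Path | None = None,
             resume: bool = True, progress: bool = False,
             estimates_out: str | Path | None = None) -> pd.DataFrame:
    """Run a list of scenarios, writing summary rows incrementally.

    With ``resume`` and an existing output table, scenarios whose label is
    already present are skipped, so an interrupted grid can be restarted
    with the same config and continue deterministically.
    """
    out = Path(out) if out is not None else None
    done: set[str] = set()
    tables: list[pd.DataFrame] = []
    if out is not None and out.exists() and resume:
        prev = pd.read_csv(out)
        tables.append(prev)
        done = set(prev["label"].astype(str))
    est_tables: list[pd.DataFrame] = []
    for sc in scenarios:
        if sc.label and sc.label in done:
            continue
        if progress:
            print(f"running scenario {sc.label!r}", flush=True)
        res = run_scenario(sc, progress=progress)
        tables.append(res.to_rows())
        if estimates_out is not None:
            est_tables.append(res.estimates.assign(label=sc.label))
        if out is not None:
            pd.concat(tables, ignore_index=True).to_csv(out, index=False)
    result = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    if estimates_out is not None and est_tables:
        pd.concat(est_tables, ignore_index=True).to_csv(estimates_out, index=False)
    return result
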