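"""Scenario configuration files and the run manifest.

Config files are flat INI-style key-value text with sections ``[cohort]``,
``[effects]``, ``[refusal]`` and ``[run]``.  Every key has a default (the
standard design constants), so an empty file is a valid config.  Keys in
the ``[refusal]`` section (and ``model`` in ``[run]``) accept comma lists;
the grid is their Cartesian product, with redundant sign combinations of
the zero-correlation tier collapsed.

The manifest records everything needed to re-create a result table
byte-for-byte: the config hash, base seed, package version and the derived
per-scenario seeds.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import __version__
from .cohort import CohortParams, RefusalSpec
from .experiment import Scenario

__all__ = ["default_config", "load_config", "build_scenarios", "scenario_seed",
           "write_manifest"]

DEFAULTS = {
    "cohort": {
        "J": "620", "K": "25", "gamma_c": "1.2", "lambda_c": "36",
        "gamma_m": "1.2", "lambda_m": "55", "sigma2_eps": "0.6",
        "sigma2_u": "0.2", "T_max": "3", "icc_label": "0.025",
    },
    "effects": {"beta": "-0.32"},
    "refusal": {
        "p": "0", "q": "0", "tier_p": "zero", "tier_q": "zero",
        "sign_p": "negative", "sign_q": "negative",
    },
    "run": {
        "model": "lognormal", "methods": "itt, pp, 2sps, 2sri",
        "reps": "1000", "base_seed": "0", "recruitment_method": "1",
        "alpha": "0.05",
    },
}

#: variance pairs the two intra-cluster-correlation settings stand for
ICC_SETTINGS = {"0.025": (0.6, 0.2), "0.05": (0.57, 0.27)}


def default_config() -> configparser.ConfigParser:
    cp = configparser.ConfigParser()
    cp.read_dict(DEFAULTS)
    return cp


def load_config(path: str | Path | None = None) -> configparser.ConfigParser:
    """Read a config file over the baked-in defaults."""
    cp = default_config()
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        cp.read(path)
    return cp


def _list(raw: str) -> list[str]:
    return [tok.strip() for tok in raw.split(",") if tok.strip()]


def scenario_seed(base_seed: int, index: int) -> int:
    """Deterministic per-scenario seed below 2**31."""
    return int(np.random.SeedSequence((base_seed, index)).generate_state(1)[0] % (2**31))


def build_scenarios(cp: configparser.ConfigParser) -> list[Scenario]:
    """Expand a config into the Cartesian grid of scenarios."""
    coh = cp["cohort"]
    icc_label = coh.get("icc_label")
    sigma2_eps, sigma2_u = coh.getfloat("sigma2_eps"), coh.getfloat("sigma2_u")
    params = CohortParams(
        J=coh.getint("J"), K=coh.getint("K"),
        gamma_c=coh.getfloat("gamma_c"), lambda_c=coh.getfloat("lambda_c"),
        gamma_m=coh.getfloat("gamma_m"), lambda_m=coh.getfloat("lambda_m"),
        sigma2_eps=sigma2_eps, sigma2_u=sigma2_u,
        beta=cp["effects"].getfloat("beta"),
        T_max=coh.getfloat("T_max"), icc_label=icc_label,
    )
    run = cp["run"]
    base_seed = run.getint("base_seed")
    methods = tuple(m.lower() for m in _list(run.get("methods")))
    reps = run.getint("reps")
    alpha = run.getfloat("alpha")
    rm = run.getint("recruitment_method")
    ref = cp["refusal"]

    combos = []
    for model in _list(run.get("model")):
        for p in _list(ref.get("p")):
            for tier_p in _list(ref.get("tier_p")):
                for sign_p in _list(ref.get("sign_p")):
                    for q in _list(ref.get("q")):
                        for tier_q in _list(ref.get("tier_q")):
                            for sign_q in _list(ref.get("sign_q")):
                                combos.append((model, float(p), tier_p, sign_p,
                                               float(q), tier_q, sign_q))
    # the zero tier (and zero mean) makes the sign irrelevant: collapse dupes
    seen, scenarios = set(), []
    for model, p, tier_p, sign_p, q, tier_q, sign_q in combos:
        if tier_p == "zero" or p == 0.0:
            sign_p = "negative"
        if tier_q == "zero" or q == 0.0:
            sign_q = "negative"
        key = (model, p, tier_p, sign_p, q, tier_q, sign_q)
        if key in seen:
            continue
        seen.add(key)
        label = f"p{p:g}_{tier_p}_{sign_p}_q{q:g}_{tier_q}_{sign_q}_{model}"
        scenarios.append(Scenario(
            params=params,
            refusal=RefusalSpec(p=p, q=q, tier_p=tier_p, tier_q=tier_q,
                                sign_p=sign_p, sign_q=sign_q),
            model=model, methods=methods, reps=reps,
            base_seed=scenario_seed(base_seed, len(scenarios)),
            recruitment_method=rm, alpha=alpha, label=label,
        ))
    return scenarios


def config_hash(cp: configparser.ConfigParser) -> str:
    payload = json.dumps({s: dict(cp[s]) for s in cp.sections()}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(path: str | Path, cp: configparser.ConfigParser,
                   scenarios: list[Scenario], extra: dict | None = None) -> dict:
    manifest = {
        "package_version": __version__,
        "config_hash": config_hash(cp),
        "base_seed": cp["run"].getint("base_seed"),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_scenarios": len(scenarios),
        "scenario_seeds": {sc.label: sc.base_seed for sc in scenarios},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
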