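"""Deterministic and probabilistic sensitivity analysis.

Parameters are addressed by dotted paths into the (spec, inputs) pair,
e.g. ``spec.utilities[0]`` or
``inputs.control.event_models['HHF'].coefficients['intercept']``.
Each :class:`ParameterDistribution` carries a sampling family for PSA
(beta for probabilities/utilities, gamma or log-normal for rates,
Dirichlet for transition-matrix rows, normal for unconstrained
coefficients, fixed to pin a value) and optional deterministic low/high
bounds for one-way DSA.

PSA draws one independent random substream per iteration from a master
seed, so results do not depend on evaluation order.  Intervals are
percentile-based (2.5/97.5) over the default 1000 iterations.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import ModelInputs, ModelSpec

_TOKEN = re.compile(r"\.?([A-Za-z_][A-Za-z0-9_]*)|\[\s*'([^']*)'\s*\]"
                    r"|\[\s*\"([^\"]*)\"\s*\]|\[\s*(-?\d+)\s*\]")


def _tokenize(path: str) -> list:
    tokens, pos = [], 0
    while pos < len(path):
        m = _TOKEN.match(path, pos)
        if not m:
            raise ValueError(f"cannot parse parameter path {path!r} at {pos}")
        attr, key1, key2, idx = m.groups()
        if attr is not None:
            tokens.append(("attr", attr))
        elif idx is not None:
            tokens.append(("index", int(idx)))
        else:
            tokens.append(("key", key1 if key1 is not None else key2))
        pos = m.end()
    return tokens


def _get(obj, token):
    kind, val = token
    return getattr(obj, val) if kind == "attr" else obj[val]


def _set(obj, token, value):
    """Assign in place where possible; tuples are rebuilt and returned."""
    kind, val = token
    if isinstance(obj, tuple):
        lst = list(obj)
        lst[val] = value
        return tuple(lst)
    if kind == "attr":
        setattr(obj, val, value)
    else:
        obj[val] = value
    return obj


def get_parameter(namespace: Mapping, path: str):
    tokens = _tokenize(path)
    obj = namespace[tokens[0][1]]
    for token in tokens[1:]:
        obj = _get(obj, token)
    return obj


def set_parameter(namespace: dict, path: str, value) -> None:
    tokens = _tokenize(path)

    def rec(obj, toks):
        if len(toks) == 1:
            return _set(obj, toks[0], value)
        child = _get(obj, toks[0])
        new_child = rec(child, toks[1:])
        if new_child is not child:
            return _set(obj, toks[0], new_child)
        return obj

    root = namespace[tokens[0][1]]
    new_root = rec(root, tokens[1:])
    namespace[tokens[0][1]] = new_root


@dataclass
class ParameterDistribution:
    """Sampling and DSA description of one uncertain parameter."""

    path: str
    family: str = "fixed"  # beta | gamma | normal | lognormal | dirichlet | fixed
    params: dict = field(default_factory=dict)
    dsa_low: float | Sequence | None = None
    dsa_high: float | Sequence | None = None

    def __post_init__(self):
        if self.family not in ("beta", "gamma", "normal", "lognormal", "dirichlet", "fixed"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if (self.dsa_low is not None and self.dsa_high is not None
                and np.isscalar(self.dsa_low) and np.isscalar(self.dsa_high)
                and self.dsa_low > self.dsa_high):
            raise ValueError("dsa_low must not exceed dsa_high")

    def sample(self, rng: np.random.Generator):
        p = self.params
        if self.family == "fixed":
            return None  # keep base value
        if self.family == "beta":
            return float(rng.beta(p["a"], p["b"]) * p.get("scale", 1.0) + p.get("loc", 0.0))
        if self.family == "gamma":
            return float(rng.gamma(p["shape"], p["scale"]))
        if self.family == "normal":
            return float(rng.normal(p["mean"], p["sd"]))
        if self.family == "lognormal":
            return float(rng.lognormal(p["mu"], p["sigma"]))
        if self.family == "dirichlet":
            return rng.dirichlet(np.asarray(p["alpha"], dtype=float))
        raise AssertionError


def beta_from_mean_se(mean: float, se: float) -> dict:
    """Method-of-moments beta hyperparameters for a probability/utility."""
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must lie in (0, 1)")
    nu = mean * (1.0 - mean) / se**2 - 1.0
    if nu <= 0:
        raise ValueError("se too large for a beta distribution")
    return {"a": mean * nu, "b": (1.0 - mean) * nu}


def _apply(spec: ModelSpec, inputs: ModelInputs, assignments: Mapping[str, object]):
    ns = {"spec": copy.deepcopy(spec), "inputs": copy.deepcopy(inputs)}
    for path, value in assignments.items():
        if value is not None:
            set_parameter(ns, path, value)
    return ns["spec"], ns["inputs"]


def run_dsa(spec: ModelSpec, inputs: ModelInputs,
            distributions: Sequence[ParameterDistribution],
            outcome_fn: Callable[[ModelSpec, ModelInputs], float]) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis (tornado table).

    Each parameter with DSA bounds is set to its low and high value in turn,
    all others at base; rows are sorted by descending outcome range.
    """
    with_bounds = [d for d in distributions if d.dsa_low is not None and d.dsa_high is not None]
    if not with_bounds:
        raise ValueError("no parameters with DSA bounds")
    base = float(outcome_fn(spec, inputs))
    rows = []
    for dist in with_bounds:
        lo_spec, lo_inputs = _apply(spec, inputs, {dist.path: dist.dsa_low})
        hi_spec, hi_inputs = _apply(spec, inputs, {dist.path: dist.dsa_high})
        low = float(outcome_fn(lo_spec, lo_inputs))
        high = float(outcome_fn(hi_spec, hi_inputs))
        rows.append({"parameter": dist.path, "low_result": low, "base_result": base,
                     "high_result": high, "range": abs(high - low)})
    return (pd.DataFrame(rows).sort_values("range", ascending=False, kind="mergesort")
            .reset_index(drop=True))


@dataclass
class PsaResult:
    """Per-iteration outcomes with percentile summaries."""

    iterations: pd.DataFrame
    summary: pd.DataFrame  # index outcome; columns mean, lo, hi
    seed: int
    n_iter: int


def run_psa(spec: ModelSpec, inputs: ModelInputs,
            distributions: Sequence[ParameterDistribution],
            outcome_fn: Callable[[ModelSpec, ModelInputs], Mapping[str, float]],
            n_iter: int = 1000, seed: int = 0,
            keep_iterations: bool = True) -> PsaResult:
    """Probabilistic sensitivity analysis.

    Each iteration redraws every parameter from its distribution (one
    independent substream per iteration) and re-evaluates ``outcome_fn``;
    summaries are the mean and the 2.5/97.5 percentile interval over
    exactly ``n_iter`` iterations.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_iter)
    rows = []
    for child in streams:
        rng = np.random.default_rng(child)
        assignments = {d.path: d.sample(rng) for d in distributions}
        it_spec, it_inputs = _apply(spec, inputs, assignments)
        rows.append(dict(outcome_fn(it_spec, it_inputs)))
    iterations = pd.DataFrame(rows)
    summary = pd.DataFrame({
        "mean": iterations.mean(),
        "lo": iterations.quantile(0.025),
        "hi": iterations.quantile(0.975),
    })
    return PsaResult(iterations=iterations if keep_iterations else iterations.iloc[0:0],
                     summary=summary, seed=seed, n_iter=n_iter)


def summarize_psa(result: PsaResult, trial_counts: Mapping[str, float]) -> pd.DataFrame:
    """Absolute/relative deviation of PSA mean outcomes from trial counts.

    Uses the external-validation difference definitions; the
    ``within_20pct`` flag marks outcomes whose probabilistic mean deviates
    by less than 20% from the observed count.
    """
    rows = []
    for outcome, trial in trial_counts.items():
        if outcome not in result.summary.index:
            raise KeyError(f"PSA result has no outcome {outcome!r}")
        mean = float(result.summary.loc[outcome, "mean"])
        absolute = abs(trial - mean)
        rel = 100.0 * absolute / abs(trial) if trial != 0 else float("nan")
        rows.append({"outcome": outcome, "trial": float(trial), "psa_mean": mean,
                     "absolute": absolute, "relative_pct": rel,
                     "within_20pct": bool(rel < 20.0) if trial != 0 else False})
    return pd.DataFrame(rows)
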