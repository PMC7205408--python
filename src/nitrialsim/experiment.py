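"""Monte-Carlo engine: non-inferiority decisions, type-I error and power.

Non-inferiority is concluded when the upper bound of the two-sided confidence
interval for the risk difference lies strictly below the margin. Running many
simulated trials under a fixed scenario and tallying the conclusion rate gives
the empirical type-I error (when the true effect equals the margin) or the
empirical power (when the true effect is zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import EffectEstimate, EstimationError, estimate
from .scenarios import Destination, ScenarioSpec, scenario_id
from .simulate import EffectParams, simulate_trial

logger = logging.getLogger("nitrialsim")

METHODS = ("ITT", "PP", "IPW", "IV")

#: How iterations whose estimator failed enter the NI-conclusion rate:
#: "exclude" drops them from the denominator; "not_ni" counts them as failing
#: to conclude non-inferiority (conservative).
FAILURE_POLICIES = ("exclude", "not_ni")


@dataclass(frozen=True)
class NIDecision:
    """Outcome of the non-inferiority test for one estimate."""

    noninferior: bool
    margin: float
    ci_upper_used: float


def test_noninferiority(estimate: EffectEstimate, margin: float) -> NIDecision:
    """Strict rule: non-inferior iff the CI upper bound is below the margin."""
    if margin <= 0:
        raise ValueError("non-inferiority margin must be positive")
    return NIDecision(
        noninferior=bool(estimate.ci_upper < margin),
        margin=margin,
        ci_upper_used=estimate.ci_upper,
    )


@dataclass
class ExperimentResult:
    """Aggregate of one (scenario, adherence, method) Monte-Carlo cell."""

    scenario: str
    adherence: float
    method: str
    n_per_arm: int
    mean_estimate: float
    ni_rate: float
    mc_se: float
    iterations: int
    failed: int
    applicable: bool = True


def _child_rng(master_seed: int, iteration: int) -> np.random.Generator:
    """Independent per-iteration stream; the iteration index is mixed into the
    seed so results do not depend on execution order."""
    return np.random.default_rng([master_seed, iteration])


def run_experiment(
    spec: ScenarioSpec,
    methods: tuple[str, ...] | list[str],
    adherence_grid,
    n_per_arm: int,
    params: EffectParams,
    margin: float = 0.1,
    iterations: int = 1000,
    master_seed: int = 0,
    ci_level: float = 0.95,
    adherence_mode: str = "threshold",
    adherence_link: str = "logit",
    covariates: list[int] | None = None,
    ipw_ci_method: str = "sandwich",
    failure_policy: str = "exclude",
    log_every: int = 0,
) -> list[ExperimentResult]:
    """Estimate the NI-conclusion rate for each (adherence, method) cell.

    For each adherence level, ``iterations`` independent trials are simulated
    (child seeds derived from ``master_seed`` and the iteration index, shared
    across adherence levels as common random numbers) and analyzed with every
    requested method against the same margin. IV is recorded as not applicable
    for alternative-destination scenarios, where the received treatment is not
    binary.
    """
    methods = tuple(m.upper() for m in methods)
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if margin <= 0:
        raise ValueError("non-inferiority margin must be positive")
    if failure_policy not in FAILURE_POLICIES:
        raise ValueError(f"unknown failure policy {failure_policy!r}")
    adherence_grid = [float(r) for r in np.atleast_1d(adherence_grid)]
    for rho in adherence_grid:
        if not 0.0 <= rho <= 1.0:
            raise ValueError(f"adherence value {rho} outside [0, 1]")

    label = scenario_id(spec)
    iv_applicable = spec.destination is not Destination.ALTERNATIVE
    results: list[ExperimentResult] = []
    for rho in adherence_grid:
        estimates: dict[str, list[float]] = {m: [] for m in methods}
        conclusions: dict[str, list[bool]] = {m: [] for m in methods}
        failures: dict[str, int] = {m: 0 for m in methods}
        for it in range(iterations):
            rng = _child_rng(master_seed, it)
            trial = simulate_trial(
                spec, n_per_arm, rho, params, seed=rng,
                mode=adherence_mode, link=adherence_link,
            )
            for m in methods:
                if m == "IV" and not iv_applicable:
                    continue
                try:
                    if m == "IPW":
                        est = estimate(trial, m, ci_level=ci_level,
                                       covariates=covariates, ci_method=ipw_ci_method,
                                       rng=rng)
                    else:
                        est = estimate(trial, m, ci_level=ci_level)
                except EstimationError:
                    failures[m] += 1
                    continue
                estimates[m].append(est.risk_difference)
                conclusions[m].append(test_noninferiority(est, margin).noninferior)
            if log_every and (it + 1) % log_every == 0:
                logger.info("scenario=%s rho=%.2f iteration %d/%d",
                            label, rho, it + 1, iterations)
        for m in methods:
            if m == "IV" and not iv_applicable:
                results.append(ExperimentResult(
                    scenario=label, adherence=rho, method=m, n_per_arm=n_per_arm,
                    mean_estimate=float("nan"), ni_rate=float("nan"),
                    mc_se=float("nan"), iterations=iterations,
                    failed=iterations, applicable=False,
                ))
                continue
            n_ok = len(conclusions[m])
            n_ni = int(np.sum(conclusions[m]))
            if failure_policy == "exclude":
                denom = n_ok
            else:
                denom = iterations
            ni_rate = n_ni / denom if denom > 0 else float("nan")
            mc_se = (
                float(np.sqrt(ni_rate * (1 - ni_rate) / denom))
                if denom > 0 else float("nan")
            )
            results.append(ExperimentResult(
                scenario=label, adherence=rho, method=m, n_per_arm=n_per_arm,
                mean_estimate=float(np.mean(estimates[m])) if n_ok else float("nan"),
                ni_rate=ni_rate, mc_se=mc_se,
                iterations=iterations, failed=failures[m],
            ))
    return results


_SUMMARY_COLUMNS = [
    "scenario", "adherence", "method", "n_per_arm",
    "mean_estimate", "ni_rate", "mc_se", "iterations", "failed",
]


def summarize(results: list[ExperimentResult]) -> pd.DataFrame:
    """One row per (scenario, adherence, method), deterministically sorted."""
    if not results:
        return pd.DataFrame(columns=_SUMMARY_COLUMNS)
    df = pd.DataFrame([
        {col: getattr(r, col) for col in _SUMMARY_COLUMNS} for r in results
    ])
    return df.sort_values(["scenario", "adherence", "method"]).reset_index(drop=True)


__all__ = [
    "METHODS",
    "FAILURE_POLICIES",
    "NIDecision",
    "ExperimentResult",
    "test_noninferiority",
    "run_experiment",
    "summarize",
]
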