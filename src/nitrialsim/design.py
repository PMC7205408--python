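"""Sample-size and power tools for non-inferiority designs with non-adherence.

The closed-form sample size is the unpooled normal-approximation formula for
the difference of two proportions against a non-inferiority margin M::

    n/arm = ceil( (z_{1-alpha} + z_{1-beta})^2 [p_c(1-p_c) + p_e(1-p_e)]
                  / (M - (p_e - p_c))^2 )

With p_c = p_e = 0.4, M = 0.1, one-sided alpha = 0.025 and 90% power this
gives 505 participants per arm. Under non-adherence the closed form no longer
applies, so power is estimated by Monte-Carlo simulation and the required
sample size by bisection on the empirical power curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .experiment import run_experiment
from .scenarios import ScenarioSpec, scenario_id
from .simulate import EffectParams


class BracketError(ValueError):
    """The requested power is not attainable within the supplied n bounds."""


def closed_form_n(
    p_control: float,
    p_experimental: float,
    margin: float,
    alpha_one_sided: float = 0.025,
    power: float = 0.9,
) -> int:
    """Participants per arm under full adherence (unpooled-variance formula)."""
    for name, p in (("p_control", p_control), ("p_experimental", p_experimental)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name} must be in (0, 1)")
    if margin <= 0:
        raise ValueError("margin must be positive")
    if not 0.0 < alpha_one_sided < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must be in (0, 1)")
    effect = p_experimental - p_control
    if margin - effect <= 1e-12:
        raise ValueError(
            "design infeasible: margin must exceed the assumed true risk difference"
        )
    z_a = norm.ppf(1.0 - alpha_one_sided)
    z_b = norm.ppf(power)
    variance = p_control * (1 - p_control) + p_experimental * (1 - p_experimental)
    n = (z_a + z_b) ** 2 * variance / (margin - effect) ** 2
    return int(math.ceil(n - 1e-9))


def empirical_power(
    spec: ScenarioSpec,
    method: str,
    n_per_arm: int,
    rho: float,
    params: EffectParams,
    margin: float = 0.1,
    iterations: int = 1000,
    seed: int = 0,
    **engine_kwargs,
) -> tuple[float, float]:
    """Monte-Carlo power (and its MC standard error) for one design cell.

    Power is defined under truly equivalent treatments, so ``params`` must
    carry ``true_effect = 0``.
    """
    if params.true_effect != 0.0:
        raise ValueError("power studies require params.true_effect == 0")
    (res,) = run_experiment(
        spec, [method], [rho], n_per_arm, params,
        margin=margin, iterations=iterations, master_seed=seed, **engine_kwargs,
    )
    return res.ni_rate, res.mc_se


@dataclass
class PowerCurve:
    """Empirical power across an adherence grid for one scenario and method."""

    scenario: str
    method: str
    n_per_arm: int
    margin: float
    iterations: int
    rows: list[tuple[float, float, float]]  # (adherence, power, mc_se)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=["adherence", "power", "mc_se"])
        df.insert(0, "n_per_arm", self.n_per_arm)
        df.insert(0, "method", self.method)
        df.insert(0, "scenario", self.scenario)
        return df


def power_curve(
    spec: ScenarioSpec,
    method: str,
    n_per_arm: int,
    adherence_grid,
    params: EffectParams,
    margin: float = 0.1,
    iterations: int = 1000,
    seed: int = 0,
    **engine_kwargs,
) -> PowerCurve:
    """Empirical power at each adherence level (true effect forced to zero)."""
    if params.true_effect != 0.0:
        raise ValueError("power studies require params.true_effect == 0")
    grid = sorted(float(r) for r in np.atleast_1d(adherence_grid))
    if len(set(grid)) != len(grid):
        raise ValueError("adherence grid values must be distinct")
    results = run_experiment(
        spec, [method], grid, n_per_arm, params,
        margin=margin, iterations=iterations, master_seed=seed, **engine_kwargs,
    )
    rows = [(r.adherence, r.ni_rate, r.mc_se) for r in results]
    return PowerCurve(
        scenario=scenario_id(spec), method=method.upper(), n_per_arm=n_per_arm,
        margin=margin, iterations=iterations, rows=rows,
    )


def required_n(
    spec: ScenarioSpec,
    method: str,
    rho: float,
    target_power: float,
    params: EffectParams,
    margin: float = 0.1,
    iterations: int = 1000,
    seed: int = 0,
    n_bounds: tuple[int, int] = (50, 4000),
    step: int = 5,
    **engine_kwargs,
) -> tuple[int, float, float]:
    """Smallest n per arm (on a lattice of width ``step``) whose empirical
    power reaches ``target_power``, by bisection with common random numbers.

    Returns ``(n, power_at_n, mc_se_at_n)``. Raises :class:`BracketError`
    when the upper bound's power falls short of the target (and accepts the
    lower bound outright when it already meets it).
    """
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must be in (0, 1)")
    lo, hi = int(n_bounds[0]), int(n_bounds[1])
    if lo < 1 or hi <= lo:
        raise ValueError("n_bounds must satisfy 1 <= lower < upper")

    cache: dict[int, tuple[float, float]] = {}

    def power_at(n: int) -> float:
        if n not in cache:
            # same seed for every candidate n: common random numbers
            cache[n] = empirical_power(
                spec, method, n, rho, params, margin, iterations, seed,
                **engine_kwargs,
            )
        return cache[n][0]

    if power_at(hi) < target_power:
        raise BracketError(
            f"power at upper bound n={hi} is {power_at(hi):.3f} < target "
            f"{target_power}; widen n_bounds"
        )
    if power_at(lo) >= target_power:
        return lo, *cache[lo]
    # invariant: power(lo) < target <= power(hi)
    while hi - lo > step:
        mid = (lo + hi) // 2
        mid -= mid % step  # stay on the lattice
        if mid <= lo:
            mid = lo + step
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi, *cache[hi]


__all__ = [
    "BracketError",
    "PowerCurve",
    "closed_form_n",
    "empirical_power",
    "power_curve",
    "required_n",
]
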