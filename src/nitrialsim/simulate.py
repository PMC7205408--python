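"""Potential-outcomes generator for a two-arm non-inferiority trial.

One simulated trial consists of, per participant: a vector of baseline
characteristics ("confounders", Beta-distributed on [0, 1], interpretable as a
disease risk score), a Bernoulli(0.5) treatment allocation Z, an adherence
indicator, the treatment actually received A in {a0 (control), a1
(experimental), a2 (alternative, inferior to both)}, three counterfactual
binary failure outcomes Y^{a0}, Y^{a1}, Y^{a2}, and the observed outcome Y
equal to the counterfactual of the received treatment (consistency).

Counterfactual failure probabilities follow a clipped linear probability
model::

    p_a(C) = clip( mu_a + gamma * sum_k (C_k - E[C]), 0, 1 )

with mu_{a0} the baseline control failure probability, mu_{a1} = mu_{a0} +
true_effect, and mu_{a2} = max(mu_{a0}, mu_{a1}) + alt_penalty. The same slope
``gamma`` applies under all three treatments, so in the absence of clipping the
average counterfactual risk difference equals ``true_effect`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .scenarios import Arm, Destination, Direction, Mechanism, ScenarioSpec

#: Integer codes for received treatment.
A_CONTROL, A_EXPERIMENTAL, A_ALTERNATIVE = 0, 1, 2
_RECEIVED_LABELS = {A_CONTROL: "a0", A_EXPERIMENTAL: "a1", A_ALTERNATIVE: "a2"}


class ConfigurationError(ValueError):
    """Raised when effect parameters cannot define a valid trial."""


@dataclass(frozen=True)
class EffectParams:
    """Data-generating parameters of the simulated trial.

    Parameters
    ----------
    p_fail_control
        Baseline treatment-failure probability under control (default 0.4).
    true_effect
        True average risk difference of experimental vs control failure
        (0.1 for type-I-error studies, 0 for power studies).
    alt_penalty
        Excess failure probability of the alternative treatment a2 over the
        worse of the two trial treatments (default 0.1).
    confounder_outcome_slope
        Pre-clipping linear slope of failure probability on each confounder.
    confounder_adherence_slope
        Strength of the confounder's influence on the non-adherence
        propensity; used by the stochastic adherence mode only. On the
        log-odds scale under the default logistic link.
    n_confounders
        Number of independent confounders K.
    beta_shape_a, beta_shape_b
        Beta distribution shape parameters of each confounder.
    """

    p_fail_control: float = 0.4
    true_effect: float = 0.1
    alt_penalty: float = 0.1
    confounder_outcome_slope: float = 1.0
    confounder_adherence_slope: float = 3.0
    n_confounders: int = 1
    beta_shape_a: float = 2.0
    beta_shape_b: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_fail_control <= 1.0:
            raise ConfigurationError("p_fail_control must be in [0, 1]")
        if self.alt_penalty < 0:
            raise ConfigurationError("alt_penalty must be >= 0")
        if self.n_confounders < 1:
            raise ConfigurationError("n_confounders must be >= 1")
        if self.beta_shape_a <= 0 or self.beta_shape_b <= 0:
            raise ConfigurationError("Beta shape parameters must be positive")
        # The three treatment means must be valid probabilities before the
        # confounder shift is applied.
        for name, mu in zip(("control", "experimental", "alternative"), self.treatment_means()):
            if not 0.0 <= mu <= 1.0:
                raise ConfigurationError(
                    f"mean failure probability for the {name} treatment is {mu:.3f}, "
                    "outside [0, 1]; adjust p_fail_control/true_effect/alt_penalty"
                )

    @property
    def confounder_mean(self) -> float:
        """E[C] = a / (a + b) for each Beta(a, b) confounder."""
        return self.beta_shape_a / (self.beta_shape_a + self.beta_shape_b)

    def treatment_means(self) -> tuple[float, float, float]:
        """(mu_a0, mu_a1, mu_a2): mean failure probability under each treatment."""
        mu0 = self.p_fail_control
        mu1 = self.p_fail_control + self.true_effect
        mu2 = max(mu0, mu1) + self.alt_penalty
        return mu0, mu1, mu2

    def with_true_effect(self, true_effect: float) -> "EffectParams":
        return replace(self, true_effect=true_effect)


@dataclass
class TrialData:
    """One simulated trial, one row per participant.

    Invariants (checked by :meth:`validate`): the observed outcome equals the
    counterfactual of the received treatment; adherent participants received
    their allocated treatment; the alternative treatment appears only for
    non-adherent participants in alternative-destination scenarios.
    """

    spec: ScenarioSpec
    confounder: np.ndarray  # (n, K) floats in [0, 1]
    allocation: np.ndarray  # (n,) 0/1, 1 = experimental arm
    adherent: np.ndarray  # (n,) 0/1
    received: np.ndarray  # (n,) in {0, 1, 2}
    y_control: np.ndarray  # (n,) 0/1 counterfactual under a0
    y_experimental: np.ndarray  # (n,) 0/1 counterfactual under a1
    y_alternative: np.ndarray  # (n,) 0/1 counterfactual under a2
    observed: np.ndarray  # (n,) 0/1

    @property
    def n(self) -> int:
        return self.allocation.shape[0]

    @property
    def n_confounders(self) -> int:
        return self.confounder.shape[1]

    def validate(self) -> "TrialData":
        z, adh, a = self.allocation, self.adherent, self.received
        cf = np.where(
            a == A_CONTROL,
            self.y_control,
            np.where(a == A_EXPERIMENTAL, self.y_experimental, self.y_alternative),
        )
        if not np.array_equal(cf, self.observed):
            raise AssertionError("consistency violated: observed != counterfactual of received")
        allocated = np.where(z == 1, A_EXPERIMENTAL, A_CONTROL)
        if not np.array_equal(a[adh == 1], allocated[adh == 1]):
            raise AssertionError("adherent participant did not receive allocated treatment")
        if np.any((a == A_ALTERNATIVE) & (adh == 1)):
            raise AssertionError("adherent participant received the alternative treatment")
        if np.any(a == A_ALTERNATIVE) and self.spec.destination is not Destination.ALTERNATIVE:
            raise AssertionError("alternative treatment in a crossover scenario")
        if np.any((self.confounder < 0) | (self.confounder > 1)):
            raise AssertionError("confounder values outside [0, 1]")
        return self

    def to_frame(self) -> pd.DataFrame:
        """Flat per-participant table (columns id, z, c1..cK, adherent,
        received, y0, y1, y2, y) for inspection and cross-language testing."""
        data: dict[str, np.ndarray | list[str]] = {"id": np.arange(self.n)}
        data["z"] = self.allocation
        for k in range(self.n_confounders):
            data[f"c{k + 1}"] = self.confounder[:, k]
        data["adherent"] = self.adherent
        data["received"] = [_RECEIVED_LABELS[int(a)] for a in self.received]
        data["y0"] = self.y_control
        data["y1"] = self.y_experimental
        data["y2"] = self.y_alternative
        data["y"] = self.observed
        return pd.DataFrame(data)


def _as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_population(
    n_total: int, params: EffectParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw confounders and randomized allocation for ``n_total`` participants.

    Allocation is iid Bernoulli(0.5) (each individual has a 50% chance of the
    experimental arm); confounders are iid Beta(a, b), independent of
    allocation.
    """
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    confounder = rng.beta(
        params.beta_shape_a, params.beta_shape_b, size=(n_total, params.n_confounders)
    )
    allocation = (rng.random(n_total) < 0.5).astype(np.int8)
    return confounder, allocation


def _uptake_sign(direction: Direction) -> int:
    """Sign of the confounder's effect on the probability of taking the
    *experimental* treatment. The confounder always raises failure risk
    (outcome slope positive by default), so concordant means uptake rises with
    the confounder and discordant means it falls."""
    return +1 if direction is Direction.CONCORDANT else -1


def _nonadherence_key(score: np.ndarray, allocation: np.ndarray, direction: Direction,
                      confounder_mean: float) -> np.ndarray:
    """Centered score oriented so larger values mean more non-adherence-prone
    within the participant's own arm."""
    s = _uptake_sign(direction)
    centered = score - confounder_mean
    # Experimental arm: adherence propensity rises with s * score.
    # Control arm: non-adherence (drift toward the experimental/alternative
    # treatment) rises with s * score.
    return np.where(allocation == 1, -s * centered, s * centered)


def _threshold_count(n_arm: int, rho: float) -> int:
    return max(0, math.ceil((1.0 - rho) * n_arm - 1e-12))


def _solve_intercept(key: np.ndarray, slope: float, target: float, link: str) -> np.ndarray:
    """Per-participant non-adherence probabilities with the arm-level mean
    calibrated to ``target`` by monotone bisection on the intercept."""
    if link == "logit":
        def mean_p(lam: float) -> float:
            return float(np.mean(expit(lam + slope * key)))
        lo, hi = -40.0, 40.0
    elif link == "linear":
        def mean_p(lam: float) -> float:
            return float(np.mean(np.clip(lam + slope * key, 0.0, 1.0)))
        lo, hi = -1.0 - abs(slope), 2.0 + abs(slope)
    else:
        raise ValueError(f"unknown adherence link {link!r}")
    if target <= mean_p(lo):
        lam = lo
    elif target >= mean_p(hi):
        lam = hi
    else:
        lam = brentq(lambda l: mean_p(l) - target, lo, hi, xtol=1e-12)
    if link == "logit":
        return expit(lam + slope * key)
    return np.clip(lam + slope * key, 0.0, 1.0)


def adherence_status(
    confounder: np.ndarray,
    allocation: np.ndarray,
    spec: ScenarioSpec,
    rho: float,
    params: EffectParams,
    mode: str = "threshold",
    rng: np.random.Generator | None = None,
    link: str = "logit",
) -> np.ndarray:
    """Adherence flags (1 = received allocated treatment) for one trial.

    Only arms named in ``spec.nonadherent_arms`` can contain non-adherent
    participants; within each targeted arm the adherence proportion is ``rho``
    exactly in ``"threshold"`` mode and in expectation in ``"stochastic"``
    mode.

    Confounded scenarios: threshold mode marks the ``ceil((1-rho)*n_arm)``
    participants with the most extreme confounder score in the scenario's
    direction as non-adherent (the mean of the K confounders is the score);
    stochastic mode draws non-adherence from a propensity that is monotone in
    the same score, with the intercept solved so the arm-level mean matches
    ``rho`` (``link="logit"`` by default, ``"linear"`` for a clipped linear
    propensity). Non-confounded scenarios: threshold mode picks an
    exact-count uniformly random subset, stochastic mode is iid
    Bernoulli(1-rho); both are independent of the confounders.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("adherence proportion rho must be in [0, 1]")
    if mode not in ("threshold", "stochastic"):
        raise ValueError(f"unknown adherence mode {mode!r}")
    rng = _as_generator(rng)
    confounder = np.atleast_2d(np.asarray(confounder, dtype=float))
    if confounder.shape[0] != len(allocation):
        confounder = confounder.T
    n = len(allocation)
    adherent = np.ones(n, dtype=np.int8)

    targeted_arms = {
        Arm.EXPERIMENTAL: (1,),
        Arm.CONTROL: (0,),
        Arm.BOTH: (0, 1),
    }[spec.nonadherent_arms]

    score = confounder.mean(axis=1)
    for z in targeted_arms:
        members = np.flatnonzero(allocation == z)
        n_arm = members.size
        if n_arm == 0:
            continue
        if spec.mechanism is Mechanism.NON_CONFOUNDED:
            if mode == "threshold":
                count = _threshold_count(n_arm, rho)
                chosen = rng.permutation(members)[:count]
                adherent[chosen] = 0
            else:
                flips = rng.random(n_arm) < (1.0 - rho)
                adherent[members[flips]] = 0
        else:
            key = _nonadherence_key(score[members], np.full(n_arm, z),
                                    spec.direction, params.confounder_mean)
            if mode == "threshold":
                count = _threshold_count(n_arm, rho)
                if count > 0:
                    order = np.argsort(key, kind="stable")[::-1]  # most prone first
                    adherent[members[order[:count]]] = 0
            else:
                if rho == 1.0:
                    continue
                p_nonadh = _solve_intercept(
                    key, params.confounder_adherence_slope, 1.0 - rho, link
                )
                flips = rng.random(n_arm) < p_nonadh
                adherent[members[flips]] = 0
    return adherent


def received_treatment(
    allocation: np.ndarray, adherent: np.ndarray, spec: ScenarioSpec
) -> np.ndarray:
    """Treatment actually received: allocated if adherent, else the opposite
    arm's treatment (crossover) or the alternative treatment a2."""
    allocation = np.asarray(allocation)
    adherent = np.asarray(adherent)
    if allocation.shape != adherent.shape:
        raise ValueError("allocation and adherent must have the same length")
    allocated = np.where(allocation == 1, A_EXPERIMENTAL, A_CONTROL)
    if spec.destination is Destination.CROSSOVER:
        off_protocol = np.where(allocation == 1, A_CONTROL, A_EXPERIMENTAL)
    else:
        off_protocol = np.full_like(allocated, A_ALTERNATIVE)
    return np.where(adherent == 1, allocated, off_protocol).astype(np.int8)


def counterfactual_probs(
    confounder: np.ndarray, params: EffectParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-individual failure probabilities (p0, p1, p2) under each treatment.

    p_a(C) = clip(mu_a + gamma * sum_k (C_k - E[C]), 0, 1); the shared slope
    means the average counterfactual contrast p1 - p0 equals ``true_effect``
    wherever no clipping occurs.
    """
    confounder = np.atleast_2d(np.asarray(confounder, dtype=float))
    mu0, mu1, mu2 = params.treatment_means()
    shift = params.confounder_outcome_slope * (
        confounder - params.confounder_mean
    ).sum(axis=1)
    p0 = np.clip(mu0 + shift, 0.0, 1.0)
    p1 = np.clip(mu1 + shift, 0.0, 1.0)
    p2 = np.clip(mu2 + shift, 0.0, 1.0)
    return p0, p1, p2


def draw_outcomes(
    probs: tuple[np.ndarray, np.ndarray, np.ndarray],
    received: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw the three counterfactual outcomes (independent Bernoulli per
    individual) and select the observed outcome by consistency."""
    p0, p1, p2 = probs
    n = len(received)
    y0 = (rng.random(n) < p0).astype(np.int8)
    y1 = (rng.random(n) < p1).astype(np.int8)
    y2 = (rng.random(n) < p2).astype(np.int8)
    observed = np.where(
        received == A_CONTROL, y0, np.where(received == A_EXPERIMENTAL, y1, y2)
    ).astype(np.int8)
    return y0, y1, y2, observed


def simulate_trial(
    spec: ScenarioSpec,
    n_per_arm: int,
    rho: float,
    params: EffectParams | None = None,
    seed=None,
    mode: str = "threshold",
    link: str = "logit",
) -> TrialData:
    """Simulate one complete trial of expected size ``2 * n_per_arm``.

    Allocation is Bernoulli(0.5), so ``n_per_arm`` is the *expected* arm size.
    The same seed always reproduces the identical trial.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    params = params or EffectParams()
    rng = _as_generator(seed)
    confounder, allocation = draw_population(2 * n_per_arm, params, rng)
    adherent = adherence_status(confounder, allocation, spec, rho, params, mode, rng, link)
    received = received_treatment(allocation, adherent, spec)
    probs = counterfactual_probs(confounder, params)
    y0, y1, y2, observed = draw_outcomes(probs, received, rng)
    return TrialData(
        spec=spec,
        confounder=confounder,
        allocation=allocation,
        adherent=adherent,
        received=received,
        y_control=y0,
        y_experimental=y1,
        y_alternative=y2,
        observed=observed,
    ).validate()


__all__ = [
    "A_CONTROL",
    "A_EXPERIMENTAL",
    "A_ALTERNATIVE",
    "ConfigurationError",
    "EffectParams",
    "TrialData",
    "draw_population",
    "adherence_status",
    "received_treatment",
    "counterfactual_probs",
    "draw_outcomes",
    "simulate_trial",
]
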