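"""Risk-difference estimators for a simulated trial: ITT, PP, IPW, IV.

All four methods report the absolute risk difference (experimental minus
control failure proportion under the method's estimand) with a Wald-type
two-sided confidence interval:

- ITT compares the allocation arms as randomized (effect of assignment).
- PP compares only participants who received their allocated treatment.
- IPW reweights the per-protocol population by inverse predicted adherence
  probabilities from arm-specific logistic regressions on the confounders.
- IV is the single-instrument linear structural mean model, which for a
  binary instrument and binary treatment reduces to the Wald ratio
  (ITT contrast divided by the between-arm difference in experimental-
  treatment uptake); its variance comes from the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm

from .scenarios import Destination
from .simulate import A_EXPERIMENTAL, TrialData

#: Denominators smaller than this (absolute compliance difference) are treated
#: as a failed IV estimation rather than reported as an explosive ratio.
IV_DENOMINATOR_TOL = 0.01


class EstimationError(RuntimeError):
    """An estimator could not produce a valid estimate on this trial
    (empty analysis arm, non-converged weight model, near-zero IV
    denominator, ...). Monte-Carlo drivers catch this and record the
    iteration as failed."""


@dataclass
class EffectEstimate:
    """A risk-difference estimate with its Wald confidence interval."""

    method: str  # "ITT" | "PP" | "IPW" | "IV"
    risk_difference: float
    std_error: float
    ci_lower: float
    ci_upper: float
    n_used: int
    diagnostics: dict = field(default_factory=dict)


def _z(ci_level: float) -> float:
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")
    return float(norm.ppf(0.5 + ci_level / 2.0))


def _wald_two_sample(y1: np.ndarray, y0: np.ndarray, ci_level: float,
                     method: str) -> EffectEstimate:
    """Unpooled Wald risk difference between two binary samples."""
    n1, n0 = len(y1), len(y0)
    p1, p0 = float(np.mean(y1)), float(np.mean(y0))
    rd = p1 - p0
    se = float(np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0))
    z = _z(ci_level)
    return EffectEstimate(
        method=method,
        risk_difference=rd,
        std_error=se,
        ci_lower=rd - z * se,
        ci_upper=rd + z * se,
        n_used=n1 + n0,
        diagnostics={"p_experimental": p1, "p_control": p0, "n1": n1, "n0": n0},
    )


def estimate_itt(trial: TrialData, ci_level: float = 0.95) -> EffectEstimate:
    """Intention-to-treat: compare observed failure by randomized arm."""
    z = trial.allocation
    if not (np.any(z == 1) and np.any(z == 0)):
        raise EstimationError("ITT requires both allocation arms to be non-empty")
    return _wald_two_sample(trial.observed[z == 1], trial.observed[z == 0], ci_level, "ITT")


def estimate_pp(trial: TrialData, ci_level: float = 0.95) -> EffectEstimate:
    """Per-protocol: ITT machinery restricted to adherent participants."""
    keep = trial.adherent == 1
    z = trial.allocation[keep]
    y = trial.observed[keep]
    if not (np.any(z == 1) and np.any(z == 0)):
        raise EstimationError("per-protocol analysis has an empty adherent arm")
    est = _wald_two_sample(y[z == 1], y[z == 0], ci_level, "PP")
    return est


def fit_adherence_weights(
    trial: TrialData, covariates: list[int] | None = None
) -> np.ndarray:
    """Inverse-probability-of-adherence weights for adherent participants.

    Fits one logistic regression per allocation arm (adherent indicator on
    the selected confounders; ``covariates`` are 0-based column indices,
    default all) and returns a full-length array with
    ``w_i = 1 / P-hat(adherent | C_i, Z_i)`` for adherent participants and
    NaN elsewhere. A fully adherent arm yields constant probability 1 and
    unit weights.
    """
    if covariates is None:
        covariates = list(range(trial.n_confounders))
    if len(covariates) == 0:
        raise ValueError("covariate subset must be non-empty")
    if any(k < 0 or k >= trial.n_confounders for k in covariates):
        raise ValueError("covariate index out of range")
    weights = np.full(trial.n, np.nan)
    for z in (0, 1):
        members = np.flatnonzero(trial.allocation == z)
        if members.size == 0:
            continue
        adh = trial.adherent[members].astype(float)
        if np.all(adh == 1):
            weights[members] = 1.0
            continue
        if np.all(adh == 0):
            continue  # no adherent participants to weight in this arm
        X = sm.add_constant(trial.confounder[np.ix_(members, covariates)])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(adh, X, family=sm.families.Binomial()).fit(maxiter=100)
                probs = np.asarray(fit.fittedvalues)
        except Exception as exc:  # non-convergence, separation, singular design
            raise EstimationError(f"adherence model failed in arm Z={z}: {exc}") from exc
        if not np.all(np.isfinite(probs)):
            raise EstimationError(f"adherence model produced non-finite fits in arm Z={z}")
        adherent_members = members[adh == 1]
        p_adh = probs[adh == 1]
        if np.any(p_adh <= 1e-10):
            raise EstimationError("fitted adherence probability of an adherent "
                                  "participant is numerically zero")
        weights[adherent_members] = 1.0 / p_adh
    return weights


def _weighted_mean_and_var(y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Hajek weighted mean and its sandwich variance with weights treated as
    known."""
    sw = float(np.sum(w))
    mu = float(np.sum(w * y) / sw)
    var = float(np.sum((w * (y - mu)) ** 2) / sw**2)
    return mu, var


def estimate_ipw(
    trial: TrialData,
    covariates: list[int] | None = None,
    ci_level: float = 0.95,
    ci_method: str = "sandwich",
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> EffectEstimate:
    """Inverse-probability-weighted per-protocol risk difference.

    The point estimate is the weighted failure proportion among adherent
    experimental-arm participants minus the weighted proportion among
    adherent control-arm participants. The default interval uses a sandwich
    variance that treats the weights as known; ``ci_method="bootstrap"``
    resamples participants within arms and refits the weight model.
    """
    if ci_method not in ("sandwich", "bootstrap"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    weights = fit_adherence_weights(trial, covariates)
    keep = trial.adherent == 1
    z = trial.allocation
    arm_stats = {}
    for arm in (0, 1):
        mask = keep & (z == arm)
        if not np.any(mask):
            raise EstimationError("IPW analysis has an empty adherent arm")
        arm_stats[arm] = _weighted_mean_and_var(
            trial.observed[mask].astype(float), weights[mask]
        )
    rd = arm_stats[1][0] - arm_stats[0][0]
    se = float(np.sqrt(arm_stats[1][1] + arm_stats[0][1]))
    zq = _z(ci_level)
    used = weights[keep]
    diagnostics = {
        "min_weight": float(np.min(used)),
        "max_weight": float(np.max(used)),
        "covariates": list(covariates) if covariates is not None
        else list(range(trial.n_confounders)),
        "ci_method": ci_method,
    }
    if ci_method == "sandwich":
        lo, hi = rd - zq * se, rd + zq * se
    else:
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        boot = _bootstrap_ipw(trial, covariates, n_boot, rng)
        se = float(np.std(boot, ddof=1))
        alpha = 1.0 - ci_level
        lo = float(np.quantile(boot, alpha / 2))
        hi = float(np.quantile(boot, 1 - alpha / 2))
        lo, hi = min(lo, rd), max(hi, rd)
        diagnostics["n_boot"] = len(boot)
    return EffectEstimate(
        method="IPW",
        risk_difference=rd,
        std_error=se,
        ci_lower=lo,
        ci_upper=hi,
        n_used=int(np.sum(keep)),
        diagnostics=diagnostics,
    )


def _bootstrap_ipw(trial: TrialData, covariates, n_boot: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Within-arm nonparametric bootstrap of the IPW risk difference."""
    from dataclasses import replace as _dc_replace

    idx_by_arm = {z: np.flatnonzero(trial.allocation == z) for z in (0, 1)}
    out = []
    for _ in range(n_boot):
        take = np.concatenate([
            rng.choice(idx_by_arm[0], size=idx_by_arm[0].size, replace=True),
            rng.choice(idx_by_arm[1], size=idx_by_arm[1].size, replace=True),
        ])
        resampled = _dc_replace(
            trial,
            confounder=trial.confounder[take],
            allocation=trial.allocation[take],
            adherent=trial.adherent[take],
            received=trial.received[take],
            y_control=trial.y_control[take],
            y_experimental=trial.y_experimental[take],
            y_alternative=trial.y_alternative[take],
            observed=trial.observed[take],
        )
        try:
            w = fit_adherence_weights(resampled, covariates)
        except EstimationError:
            continue
        keep = resampled.adherent == 1
        z = resampled.allocation
        mus = {}
        ok = True
        for arm in (0, 1):
            mask = keep & (z == arm)
            if not np.any(mask):
                ok = False
                break
            mus[arm], _ = _weighted_mean_and_var(
                resampled.observed[mask].astype(float), w[mask]
            )
        if ok:
            out.append(mus[1] - mus[0])
    if len(out) < max(10, n_boot // 4):
        raise EstimationError("too few successful bootstrap resamples for the IPW interval")
    return np.asarray(out)


def estimate_iv(trial: TrialData, ci_level: float = 0.95) -> EffectEstimate:
    """Instrumental-variable (Wald ratio / linear SMM) risk difference.

    RD = [mean(Y|Z=1) - mean(Y|Z=0)] / [P(A=a1|Z=1) - P(A=a1|Z=0)], using
    randomization as the instrument; the standard error comes from the delta
    method with within-arm covariances of outcome and uptake. Only defined
    for crossover scenarios (treatment is binary a0/a1).
    """
    if trial.spec.destination is Destination.ALTERNATIVE:
        raise ValueError(
            "IV estimation applies only to crossover non-adherence "
            "(binary received treatment); this trial has an alternative-treatment arm"
        )
    z = trial.allocation
    if not (np.any(z == 1) and np.any(z == 0)):
        raise EstimationError("IV requires both allocation arms to be non-empty")
    y = trial.observed.astype(float)
    d = (trial.received == A_EXPERIMENTAL).astype(float)
    stats = {}
    for arm in (0, 1):
        mask = z == arm
        n = int(np.sum(mask))
        ybar, dbar = float(np.mean(y[mask])), float(np.mean(d[mask]))
        vy = ybar * (1 - ybar) / n
        vd = dbar * (1 - dbar) / n
        cyd = float(np.mean(y[mask] * d[mask]) - ybar * dbar) / n
        stats[arm] = (ybar, dbar, vy, vd, cyd)
    num = stats[1][0] - stats[0][0]
    den = stats[1][1] - stats[0][1]
    if abs(den) < IV_DENOMINATOR_TOL:
        raise EstimationError(
            f"compliance difference {den:.4f} is too close to zero for IV estimation"
        )
    rd = num / den
    var_num = stats[1][2] + stats[0][2]
    var_den = stats[1][3] + stats[0][3]
    cov = stats[1][4] + stats[0][4]
    var = var_num / den**2 + num**2 * var_den / den**4 - 2 * num * cov / den**3
    se = float(np.sqrt(max(var, 0.0)))
    zq = _z(ci_level)
    return EffectEstimate(
        method="IV",
        risk_difference=rd,
        std_error=se,
        ci_lower=rd - zq * se,
        ci_upper=rd + zq * se,
        n_used=trial.n,
        diagnostics={"compliance_difference": den, "itt_numerator": num},
    )


_ESTIMATOR_TABLE = {
    "ITT": estimate_itt,
    "PP": estimate_pp,
    "IV": estimate_iv,
}


def estimate(trial: TrialData, method: str, ci_level: float = 0.95,
             **kwargs) -> EffectEstimate:
    """Dispatch by method name ("ITT", "PP", "IPW", "IV")."""
    method = method.upper()
    if method == "IPW":
        return estimate_ipw(trial, ci_level=ci_level, **kwargs)
    try:
        fn = _ESTIMATOR_TABLE[method]
    except KeyError:
        raise ValueError(f"unknown estimation method {method!r}") from None
    return fn(trial, ci_level=ci_level)


__all__ = [
    "EffectEstimate",
    "EstimationError",
    "IV_DENOMINATOR_TOL",
    "estimate",
    "estimate_itt",
    "estimate_pp",
    "estimate_ipw",
    "estimate_iv",
    "fit_adherence_weights",
]
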