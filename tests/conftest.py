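import numpy as np
import pytest

from nitrialsim import EffectParams, ScenarioSpec, TrialData, parse_scenario_id
from nitrialsim.simulate import A_ALTERNATIVE, A_CONTROL, A_EXPERIMENTAL


@pytest.fixture
def default_params() -> EffectParams:
    return EffectParams()


@pytest.fixture
def null_params() -> EffectParams:
    """Truly equivalent treatments (power studies)."""
    return EffectParams(true_effect=0.0)


@pytest.fixture
def nonconf_cross() -> ScenarioSpec:
    return parse_scenario_id("both-cross-nonconf")


def make_trial(spec: ScenarioSpec, allocation, adherent, observed,
               received=None, confounder=None) -> TrialData:
    """Hand-build a consistent TrialData from explicit per-participant values.

    All three counterfactual outcomes are set equal to the observed outcome so
    the consistency invariant holds whatever treatment was received.
    """
    allocation = np.asarray(allocation, dtype=np.int8)
    adherent = np.asarray(adherent, dtype=np.int8)
    observed = np.asarray(observed, dtype=np.int8)
    n = allocation.size
    if received is None:
        allocated = np.where(allocation == 1, A_EXPERIMENTAL, A_CONTROL)
        if spec.destination.value == "cross":
            off = np.where(allocation == 1, A_CONTROL, A_EXPERIMENTAL)
        else:
            off = np.full(n, A_ALTERNATIVE)
        received = np.where(adherent == 1, allocated, off)
    received = np.asarray(received, dtype=np.int8)
    if confounder is None:
        confounder = np.full((n, 1), 0.5)
    confounder = np.atleast_2d(np.asarray(confounder, dtype=float))
    if confounder.shape[0] != n:
        confounder = confounder.T
    return TrialData(
        spec=spec,
        confounder=confounder,
        allocation=allocation,
        adherent=adherent,
        received=received,
        y_control=observed.copy(),
        y_experimental=observed.copy(),
        y_alternative=observed.copy(),
        observed=observed,
    ).validate()
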