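"""Taxonomy of non-adherence patterns in a two-arm non-inferiority trial.

A scenario is defined by four factors: which allocation arm(s) contain
non-adherent participants, what treatment the non-adherents actually receive
(the opposite arm's treatment, or a third treatment inferior to both), whether
the factors driving non-adherence also affect the outcome (confounded vs
non-confounded), and — for confounded scenarios — whether the confounder pushes
experimental-treatment uptake and treatment failure in the same direction
(concordant) or in opposite directions (discordant).

The full cross-product yields 18 valid scenarios: 3 arms x 2 destinations x
(1 non-confounded + 2 confounded directions).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Arm(str, Enum):
    """Which allocation arm(s) contain non-adherent participants."""

    EXPERIMENTAL = "exp"
    CONTROL = "ctrl"
    BOTH = "both"


class Destination(str, Enum):
    """What non-adherent participants actually receive."""

    CROSSOVER = "cross"  # the opposite arm's treatment
    ALTERNATIVE = "alt"  # a third treatment inferior to both


class Mechanism(str, Enum):
    """Whether the drivers of non-adherence also affect the outcome."""

    NON_CONFOUNDED = "nonconf"
    CONFOUNDED = "conf"


class Direction(str, Enum):
    """Sign relation between the confounder's effects on experimental-treatment
    uptake and on treatment failure (confounded scenarios only)."""

    CONCORDANT = "conc"
    DISCORDANT = "disc"
    NONE = "none"


class ScenarioError(ValueError):
    """Raised for an invalid scenario configuration or label."""


@dataclass(frozen=True)
class ScenarioSpec:
    """One non-adherence pattern.

    Parameters
    ----------
    nonadherent_arms
        Arm(s) in which non-adherence occurs.
    destination
        Treatment actually received by non-adherent participants.
    mechanism
        Whether non-adherence is driven by confounders.
    direction
        For confounded scenarios, ``CONCORDANT`` (confounder raises both the
        probability of taking the experimental treatment and the probability
        of treatment failure) or ``DISCORDANT`` (opposite signs). Must be
        ``NONE`` exactly when the mechanism is non-confounded.
    """

    nonadherent_arms: Arm
    destination: Destination
    mechanism: Mechanism
    direction: Direction = Direction.NONE

    def __post_init__(self) -> None:
        validate_scenario(self)

    @property
    def label(self) -> str:
        return scenario_id(self)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def validate_scenario(spec: ScenarioSpec) -> ScenarioSpec:
    """Return ``spec`` unchanged if its invariants hold, else raise.

    The single cross-field invariant is that ``direction`` is ``NONE`` if and
    only if ``mechanism`` is ``NON_CONFOUNDED``.
    """
    if not isinstance(spec.nonadherent_arms, Arm):
        raise ScenarioError(f"nonadherent_arms must be an Arm, got {spec.nonadherent_arms!r}")
    if not isinstance(spec.destination, Destination):
        raise ScenarioError(f"destination must be a Destination, got {spec.destination!r}")
    if not isinstance(spec.mechanism, Mechanism):
        raise ScenarioError(f"mechanism must be a Mechanism, got {spec.mechanism!r}")
    if not isinstance(spec.direction, Direction):
        raise ScenarioError(f"direction must be a Direction, got {spec.direction!r}")
    if spec.mechanism is Mechanism.NON_CONFOUNDED and spec.direction is not Direction.NONE:
        raise ScenarioError(
            "a non-confounded scenario cannot specify a confounder direction "
            f"(got direction={spec.direction.value!r})"
        )
    if spec.mechanism is Mechanism.CONFOUNDED and spec.direction is Direction.NONE:
        raise ScenarioError(
            "a confounded scenario must specify direction='conc' or 'disc'"
        )
    return spec


#: Fixed enumeration orders, chosen once for reproducible CSV output.
_ARM_ORDER = (Arm.EXPERIMENTAL, Arm.CONTROL, Arm.BOTH)
_DEST_ORDER = (Destination.CROSSOVER, Destination.ALTERNATIVE)
_MECH_DIR_ORDER = (
    (Mechanism.NON_CONFOUNDED, Direction.NONE),
    (Mechanism.CONFOUNDED, Direction.CONCORDANT),
    (Mechanism.CONFOUNDED, Direction.DISCORDANT),
)


def enumerate_scenarios() -> tuple[ScenarioSpec, ...]:
    """All 18 valid scenarios in a fixed (arm, destination, mechanism/direction)
    order: 6 non-confounded and 12 confounded patterns."""
    return tuple(
        ScenarioSpec(arm, dest, mech, direction)
        for arm in _ARM_ORDER
        for dest in _DEST_ORDER
        for mech, direction in _MECH_DIR_ORDER
    )


def scenario_id(spec: ScenarioSpec) -> str:
    """Short stable text label, unique across the 18 scenarios.

    Format: ``<arm>-<destination>-nonconf`` or ``<arm>-<destination>-conf-<dir>``,
    e.g. ``"both-cross-nonconf"`` or ``"exp-alt-conf-disc"``. Labels round-trip
    through :func:`parse_scenario_id` and are used as CSV keys and CLI values.
    """
    validate_scenario(spec)
    mech = spec.mechanism.value
    if spec.mechanism is Mechanism.CONFOUNDED:
        mech = f"conf-{spec.direction.value}"
    return f"{spec.nonadherent_arms.value}-{spec.destination.value}-{mech}"


def parse_scenario_id(label: str) -> ScenarioSpec:
    """Inverse of :func:`scenario_id`; raises :class:`ScenarioError` on an
    unknown label."""
    parts = label.strip().split("-")
    try:
        if len(parts) == 3 and parts[2] == "nonconf":
            return ScenarioSpec(Arm(parts[0]), Destination(parts[1]), Mechanism.NON_CONFOUNDED)
        if len(parts) == 4 and parts[2] == "conf":
            return ScenarioSpec(
                Arm(parts[0]), Destination(parts[1]), Mechanism.CONFOUNDED, Direction(parts[3])
            )
    except ValueError as exc:
        raise ScenarioError(f"unknown scenario label {label!r}") from exc
    raise ScenarioError(f"unknown scenario label {label!r}")


def describe(spec: ScenarioSpec) -> str:
    """One-line human-readable description of a scenario."""
    arm = {
        Arm.EXPERIMENTAL: "experimental arm only",
        Arm.CONTROL: "control arm only",
        Arm.BOTH: "both arms",
    }[spec.nonadherent_arms]
    dest = {
        Destination.CROSSOVER: "cross over to the opposite treatment",
        Destination.ALTERNATIVE: "receive an alternative treatment inferior to both",
    }[spec.destination]
    if spec.mechanism is Mechanism.NON_CONFOUNDED:
        mech = "non-adherence independent of outcome risk"
    else:
        rel = "same" if spec.direction is Direction.CONCORDANT else "opposite"
        mech = (
            "confounded non-adherence, uptake and failure effects "
            f"of the confounder in the {rel} direction"
        )
    return f"non-adherent participants in {arm} {dest}; {mech}"


__all__ = [
    "Arm",
    "Destination",
    "Mechanism",
    "Direction",
    "ScenarioSpec",
    "ScenarioError",
    "validate_scenario",
    "enumerate_scenarios",
    "scenario_id",
    "parse_scenario_id",
    "describe",
]
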