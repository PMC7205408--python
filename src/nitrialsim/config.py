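"""Run configuration: a flat, validated key-value block.

A :class:`RunConfig` collects everything a simulation sweep needs — scenarios,
methods, trial size, the adherence grid, effect parameters, the margin and CI
level, Monte-Carlo settings, and output options. Configurations load from a
flat YAML file, with CLI flags overriding file values; unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .experiment import FAILURE_POLICIES, METHODS
from .scenarios import parse_scenario_id
from .simulate import EffectParams


class ConfigError(ValueError):
    """A configuration file or override is invalid; the message names the key."""


@dataclass
class RunConfig:
    scenario: list[str] = field(default_factory=lambda: ["both-cross-nonconf"])
    methods: list[str] = field(default_factory=lambda: list(METHODS))
    n_per_arm: int = 505
    adherence_min: float = 0.6
    adherence_max: float = 1.0
    adherence_step: float = 0.05
    p_fail_control: float = 0.4
    true_effect: float = 0.1
    alt_penalty: float = 0.1
    confounder_outcome_slope: float = 1.0
    confounder_adherence_slope: float = 3.0
    n_confounders: int = 1
    beta_shape_a: float = 2.0
    beta_shape_b: float = 2.0
    margin: float = 0.1
    ci_level: float = 0.95
    iterations: int = 1000
    seed: int = 0
    out: str | None = None
    failure_policy: str = "exclude"
    ipw_ci_method: str = "sandwich"
    adherence_mode: str = "threshold"
    adherence_link: str = "logit"

    def __post_init__(self) -> None:
        if isinstance(self.scenario, str):
            self.scenario = [self.scenario]
        if isinstance(self.methods, str):
            self.methods = [self.methods]
        self.methods = [m.upper() for m in self.methods]
        for label in self.scenario:
            try:
                parse_scenario_id(label)
            except Exception as exc:
                raise ConfigError(f"scenario: {exc}") from exc
        for m in self.methods:
            if m not in METHODS:
                raise ConfigError(f"methods: unknown method {m!r}")
        if self.n_per_arm < 1:
            raise ConfigError("n_per_arm: must be >= 1")
        if not 0.0 <= self.adherence_min <= self.adherence_max <= 1.0:
            raise ConfigError("adherence_min/adherence_max: need 0 <= min <= max <= 1")
        if self.adherence_step <= 0:
            raise ConfigError("adherence_step: must be positive")
        if self.margin <= 0:
            raise ConfigError("margin: must be positive")
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigError("ci_level: must be in (0, 1)")
        if self.iterations < 1:
            raise ConfigError("iterations: must be >= 1")
        if self.failure_policy not in FAILURE_POLICIES:
            raise ConfigError(f"failure_policy: choose from {FAILURE_POLICIES}")
        if self.ipw_ci_method not in ("sandwich", "bootstrap"):
            raise ConfigError("ipw_ci_method: choose 'sandwich' or 'bootstrap'")
        if self.adherence_mode not in ("threshold", "stochastic"):
            raise ConfigError("adherence_mode: choose 'threshold' or 'stochastic'")
        if self.adherence_link not in ("logit", "linear"):
            raise ConfigError("adherence_link: choose 'logit' or 'linear'")
        try:
            self.effect_params()
        except Exception as exc:
            raise ConfigError(str(exc)) from exc

    def effect_params(self) -> EffectParams:
        return EffectParams(
            p_fail_control=self.p_fail_control,
            true_effect=self.true_effect,
            alt_penalty=self.alt_penalty,
            confounder_outcome_slope=self.confounder_outcome_slope,
            confounder_adherence_slope=self.confounder_adherence_slope,
            n_confounders=self.n_confounders,
            beta_shape_a=self.beta_shape_a,
            beta_shape_b=self.beta_shape_b,
        )

    def adherence_grid(self) -> list[float]:
        grid = []
        rho = self.adherence_min
        while rho <= self.adherence_max + 1e-9:
            grid.append(round(rho, 10))
            rho += self.adherence_step
        return grid

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELD_NAMES = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a validated RunConfig from an optional YAML file plus overrides.

    Unknown keys in either source raise :class:`ConfigError`; overrides with
    value ``None`` are ignored (unset CLI flags).
    """
    values: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        values.update(loaded)
    for key, val in (overrides or {}).items():
        if val is not None:
            values[key] = val
    unknown = set(values) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    try:
        return RunConfig(**values)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def write_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the effective configuration as flat YAML; round-trips through
    :func:`load_config`."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, default_flow_style=False, sort_keys=True)


__all__ = ["ConfigError", "RunConfig", "load_config", "write_config"]
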