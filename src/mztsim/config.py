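"""Scenario configuration: presets, validation and (de-)serialization.

A :class:`Scenario` bundles everything one simulation run needs: the growth
and repressor parameters, both sexes' rate configurations, the environmental
model and the initial zygotic states. Scenarios load from YAML (or JSON —
YAML is a superset) with unknown keys rejected and omitted keys filled from
the default preset.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .core import SEXES, GrowthConfig, InvalidParameterError, MethylState, RateSet, SexConfig
from .lifecycle import ConfigurationError, EnvModel

__all__ = ["Scenario", "PRESETS", "preset", "load_config", "save_config", "scenario_to_dict"]


@dataclass
class Scenario:
    name: str
    growth: GrowthConfig
    male: SexConfig
    female: SexConfig
    env: EnvModel
    n_generations: int = 2
    initial_states: dict[str, MethylState] = field(
        default_factory=lambda: {s: MethylState(1.0, 0.0, 0.0) for s in SEXES}
    )

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ConfigurationError("n_generations must be >= 1")
        if set(self.initial_states) != set(SEXES):
            raise ConfigurationError(f"initial_states must have keys {SEXES}")

    @property
    def sexes(self) -> dict[str, SexConfig]:
        return {"male": self.male, "female": self.female}


def _default_scenario() -> Scenario:
    """The canonical default scenario (zebrafish-level gametes).

    Post-ZGA equilibria: male X* = 0.04/0.05 = 0.80, female X* = 0.1/0.11 =
    0.909091 — the printed zebrafish gametic methylation levels 0.80/0.91.
    """
    return Scenario(
        name="table1_default",
        growth=GrowthConfig(),
        male=SexConfig("male", post_zga=RateSet(0.99, 0.04, 0.01, 0.0)),
        female=SexConfig("female", post_zga=RateSet(0.99, 0.1, 0.01, 0.0)),
        env=EnvModel(),
        n_generations=2,
    )


def _zebrafish() -> Scenario:
    s = _default_scenario()
    s.name = "zebrafish"
    return s


def _human() -> Scenario:
    # Rates pinned from the parameter-space explorer: alpha + delta = 1
    # triples whose equilibria are exactly the printed gametic levels
    # (sperm 0.27/0.50 = 0.54, oocyte 0.12/0.25 = 0.48).
    s = _default_scenario()
    s.name = "human"
    s.male = SexConfig("male", post_zga=RateSet(0.77, 0.27, 0.23, 0.0))
    s.female = SexConfig("female", post_zga=RateSet(0.87, 0.12, 0.13, 0.0))
    return s


def _hypothetical_low() -> Scenario:
    # Hypothetical poorly methylated gamete, X* = 0.03/0.10 = 0.30 (both sexes).
    s = _default_scenario()
    s.name = "hypothetical_0.30"
    s.male = SexConfig("male", post_zga=RateSet(0.93, 0.03, 0.07, 0.0))
    s.female = SexConfig("female", post_zga=RateSet(0.93, 0.03, 0.07, 0.0))
    return s


PRESETS = {
    "table1_default": _default_scenario,
    "zebrafish": _zebrafish,
    "human": _human,
    "hypothetical_0.30": _hypothetical_low,
}


def preset(name: str) -> Scenario:
    """A fresh copy of a named scenario preset."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# dict / file round-trip
# ---------------------------------------------------------------------------

def scenario_to_dict(s: Scenario) -> dict[str, Any]:
    def _sex(sc: SexConfig) -> dict[str, Any]:
        return {
            "pre_zga": asdict(sc.pre_zga),
            "post_zga": asdict(sc.post_zga),
            "alpha_env_range": list(sc.alpha_env_range),
            "delta_env_range": list(sc.delta_env_range),
        }

    return {
        "name": s.name,
        "n_generations": s.n_generations,
        "growth": asdict(s.growth),
        "male": _sex(s.male),
        "female": _sex(s.female),
        "env": {
            "mode": s.env.mode,
            "sexes": list(s.env.sexes),
            "alpha_interval": list(s.env.alpha_interval),
            "delta_interval": list(s.env.delta_interval),
            "alpha_shift": s.env.alpha_shift,
            "delta_shift": s.env.delta_shift,
            "accumulate": s.env.accumulate,
            "seed": s.env.seed,
        },
        "initial_states": {
            sx: asdict(st) for sx, st in s.initial_states.items()
        },
    }


def _merge(defaults: dict, user: Mapping, path: str = "") -> dict:
    """Recursively overlay user keys on defaults, rejecting unknown keys."""
    out = dict(defaults)
    for key, value in user.items():
        where = f"{path}{key}"
        if key not in defaults:
            raise ConfigurationError(f"unknown configuration key: {where!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, Mapping):
                raise ConfigurationError(f"{where!r} must be a mapping")
            out[key] = _merge(defaults[key], value, where + ".")
        else:
            out[key] = value
    return out


def scenario_from_dict(data: Mapping[str, Any]) -> Scenario:
    merged = _merge(scenario_to_dict(_default_scenario()), data)

    def _sex(label: str) -> SexConfig:
        d = merged[label]
        try:
            return SexConfig(
                label,
                pre_zga=RateSet(**d["pre_zga"]),
                post_zga=RateSet(**d["post_zga"]),
                alpha_env_range=tuple(d["alpha_env_range"]),
                delta_env_range=tuple(d["delta_env_range"]),
            )
        except InvalidParameterError as exc:
            raise ConfigurationError(f"invalid rates for {label!r}: {exc}") from exc

    try:
        growth = GrowthConfig(**merged["growth"])
    except InvalidParameterError as exc:
        raise ConfigurationError(f"invalid growth configuration: {exc}") from exc
    env_d = dict(merged["env"])
    env_d["sexes"] = tuple(env_d["sexes"])
    env_d["alpha_interval"] = tuple(env_d["alpha_interval"])
    env_d["delta_interval"] = tuple(env_d["delta_interval"])
    states = {
        sx: MethylState(**merged["initial_states"][sx]) for sx in SEXES
    }
    return Scenario(
        name=merged["name"],
        growth=growth,
        male=_sex("male"),
        female=_sex("female"),
        env=EnvModel(**env_d),
        n_generations=merged["n_generations"],
        initial_states=states,
    )


def load_config(path: str | Path) -> Scenario:
    """Load a scenario from YAML/JSON; an empty file yields the default preset."""
    raw = Path(path).read_text()
    try:
        data = yaml.safe_load(raw)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path} must contain a mapping at top level")
    return scenario_from_dict(data)


def save_config(scenario: Scenario, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(scenario), sort_keys=False))
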