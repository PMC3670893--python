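"""Configuration files, run manifests and seeded RNG plumbing.

A run is configured by a YAML (or JSON — YAML is a superset) file with up to
three sections mapping one-to-one onto the library types::

    simulation:            # SimulationConfig fields
      host_count: 200
      host_acceptance_threshold: 0.5
      ...
    strategy:              # non-evolving Strategy fields, plus an optional
      lifespan: 20         # explicit sex_choice mapping
      sex_choice:
        empty: 0.5
    survival:              # per-context {mean, sd}
      female_single_sex: {mean: 45.7, sd: 10.9}

Unknown keys are rejected by name; an empty file yields all defaults.  Every
CLI run writes a :class:`RunManifest` beside its outputs so that re-running
with the manifest's config and seed reproduces the outputs bit for bit.  All
randomness descends from one user-supplied seed through
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .model_core import (
    SURVIVAL_CONTEXTS,
    SimulationConfig,
    Strategy,
    SurvivalDistributions,
    default_template,
    sex_choice_keys,
)

__all__ = ["ConfigError", "RunManifest", "load_config", "save_config", "default_config_text"]


class ConfigError(ValueError):
    """A configuration file violated the schema."""


_SIMULATION_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}
_STRATEGY_FIELDS = {
    f.name for f in dataclasses.fields(Strategy) if f.name != "survival"
}


def load_config(path: str | Path) -> tuple[SimulationConfig, Strategy]:
    """Load and validate a config file; defaults fill anything omitted."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping at the top level")
    unknown = set(raw) - {"simulation", "strategy", "survival"}
    if unknown:
        raise ConfigError(f"unknown top-level section(s): {sorted(unknown)}")

    sim_raw = raw.get("simulation") or {}
    bad = set(sim_raw) - _SIMULATION_FIELDS
    if bad:
        raise ConfigError(f"unknown simulation key(s): {sorted(bad)}")
    config = SimulationConfig(**sim_raw)

    strat_raw = dict(raw.get("strategy") or {})
    sex_choice = strat_raw.pop("sex_choice", None)
    bad = set(strat_raw) - _STRATEGY_FIELDS
    if bad:
        raise ConfigError(f"unknown strategy key(s): {sorted(bad)}")

    surv_raw = raw.get("survival") or {}
    bad = set(surv_raw) - set(SURVIVAL_CONTEXTS)
    if bad:
        raise ConfigError(f"unknown survival context(s): {sorted(bad)}")
    survival_kwargs = {}
    for context, entry in surv_raw.items():
        extra = set(entry) - {"mean", "sd"}
        if extra:
            raise ConfigError(
                f"survival {context}: unknown key(s) {sorted(extra)}")
        defaults = SurvivalDistributions().params(context)
        survival_kwargs[context] = (
            float(entry.get("mean", defaults[0])),
            float(entry.get("sd", defaults[1])),
        )

    template = default_template(config.info_level)
    template = replace(template, **strat_raw)
    if survival_kwargs:
        template = replace(template,
                           survival=SurvivalDistributions(**survival_kwargs))
    if sex_choice is not None:
        keys = set(sex_choice_keys(config.info_level))
        bad = set(sex_choice) - keys
        if bad:
            raise ConfigError(
                f"sex_choice key(s) {sorted(bad)} invalid for info_level "
                f"{config.info_level!r}")
        merged = dict(template.sex_choice)
        merged.update({k: float(v) for k, v in sex_choice.items()})
        template = replace(template, sex_choice=merged)

    try:
        config.validate()
        template.validate()
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return config, template


def _config_dict(config: SimulationConfig, template: Strategy) -> dict:
    strategy = {name: getattr(template, name) for name in sorted(_STRATEGY_FIELDS)}
    strategy["sex_choice"] = {k: float(v) for k, v in template.sex_choice.items()}
    return {
        "simulation": dataclasses.asdict(config),
        "strategy": strategy,
        "survival": {
            context: {"mean": mean, "sd": sd}
            for context in SURVIVAL_CONTEXTS
            for mean, sd in [template.survival.params(context)]
        },
    }


def save_config(config: SimulationConfig, template: Strategy,
                path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(_config_dict(config, template), sort_keys=False))


def default_config_text() -> str:
    """YAML text of the full default configuration (the `config init` payload)."""
    return yaml.safe_dump(
        _config_dict(SimulationConfig(), default_template()), sort_keys=False)


@dataclass
class RunManifest:
    """Everything needed to reproduce a CLI run bit for bit."""

    command: str
    config: dict
    seed: int | None
    version: str
    outputs: list[str] = field(default_factory=list)
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc).isoformat())

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str))
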