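"""Analysis configuration: schema, validation, packaged defaults.

The packaged default configuration (``data/default.yaml``) carries the
published study inputs — the four binomial observations and beta priors,
every unit cost, the sampler settings and the scenario grid — so a run with
no user config reproduces the published analysis.  A user YAML file is
merged over the defaults key-by-key, then validated into typed objects;
validation errors name the offending field path.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .costs import UnitCosts
from .inference import BetaPrior, BinomialObservation, SamplerSettings
from .tree import DoseConvention, ProbabilityVector

__all__ = ["AnalysisConfig", "ConfigError", "load_config", "default_config", "config_hash"]


class ConfigError(ValueError):
    """A configuration field failed schema validation."""


@dataclass
class AnalysisConfig:
    """Fully validated inputs for one end-to-end analysis run."""

    observations: dict[str, BinomialObservation]
    priors: dict[str, BetaPrior]
    unit_costs: UnitCosts
    sampler: SamplerSettings
    n_patients: list[int]
    batch_sizes: list[int]
    conventions: list[DoseConvention]
    credible_level: float = 0.95
    output_dir: str = "results"
    raw: dict[str, Any] = field(default_factory=dict, repr=False)


def _merge(base: dict[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    merged = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(merged.get(key), dict):
            merged[key] = _merge(merged[key], value)
        else:
            merged[key] = value
    return merged


def _build(path: str, factory, **kwargs):
    try:
        return factory(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _raw_defaults() -> dict[str, Any]:
    text = resources.files("cinvecon").joinpath("data/default.yaml").read_text()
    return yaml.safe_load(text)


def _validate(raw: dict[str, Any]) -> AnalysisConfig:
    for section in ("observations", "priors", "sampler", "unit_costs", "scenario"):
        if section not in raw or not isinstance(raw[section], Mapping):
            raise ConfigError(f"{section}: missing or not a mapping")

    observations: dict[str, BinomialObservation] = {}
    priors: dict[str, BetaPrior] = {}
    for name in ProbabilityVector.FIELDS:
        if name not in raw["observations"]:
            raise ConfigError(f"observations.{name}: missing")
        if name not in raw["priors"]:
            raise ConfigError(f"priors.{name}: missing")
        observations[name] = _build(
            f"observations.{name}", BinomialObservation, **raw["observations"][name]
        )
        priors[name] = _build(f"priors.{name}", BetaPrior, **raw["priors"][name])

    sampler = _build("sampler", SamplerSettings, **raw["sampler"])
    unit_costs = _build("unit_costs", UnitCosts, **raw["unit_costs"])

    scenario = raw["scenario"]
    n_patients = scenario.get("n_patients", [])
    batch_sizes = scenario.get("batch_sizes", [])
    if not n_patients or any(int(n) < 0 for n in n_patients):
        raise ConfigError("scenario.n_patients: must be a nonempty list of nonnegative counts")
    if not batch_sizes or any(int(b) < 1 for b in batch_sizes):
        raise ConfigError("scenario.batch_sizes: must be a nonempty list of positive counts")
    try:
        conventions = [DoseConvention(tag) for tag in scenario.get("conventions", [])]
    except ValueError as exc:
        raise ConfigError(f"scenario.conventions: {exc}") from exc
    if not conventions:
        raise ConfigError("scenario.conventions: must name at least one dose convention")

    level = float(raw.get("credible_level", 0.95))
    if not 0.0 < level < 1.0:
        raise ConfigError(f"credible_level: must lie in (0, 1), got {level}")

    return AnalysisConfig(
        observations=observations,
        priors=priors,
        unit_costs=unit_costs,
        sampler=sampler,
        n_patients=[int(n) for n in n_patients],
        batch_sizes=[int(b) for b in batch_sizes],
        conventions=conventions,
        credible_level=level,
        output_dir=str(raw.get("output_dir", "results")),
        raw=raw,
    )


def default_config() -> AnalysisConfig:
    """The packaged configuration reproducing the published analysis."""
    return _validate(_raw_defaults())


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load a YAML config merged over the packaged defaults."""
    raw = _raw_defaults()
    if path is not None:
        with open(path) as handle:
            user = yaml.safe_load(handle) or {}
        if not isinstance(user, Mapping):
            raise ConfigError(f"{path}: top level must be a mapping")
        raw = _merge(raw, user)
    return _validate(raw)


def config_hash(config: AnalysisConfig) -> str:
    """SHA-256 over the canonical JSON of the merged raw configuration."""
    canonical = json.dumps(config.raw, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


def sampler_as_dict(settings: SamplerSettings) -> dict[str, Any]:
    return asdict(settings)
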