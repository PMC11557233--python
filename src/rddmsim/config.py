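"""Run configuration: every tunable parameter of one simulation condition.

Configurations live in nested YAML files with four sections —
``simulation`` (sizes, cycle length, seed), ``initial`` (starting
methylation distribution), ``production`` (siRNA production rule and
schedule) and ``search`` (target type and kinetic overrides) — and can
be tweaked on the command line with dotted-key overrides
(``production.production_level=500``).  ``parse(serialize(cfg))``
round-trips exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .locus_init import InitialDistributionSpec
from .sirna_dynamics import ProductionSpec
from .target_search import SearchKinetics

__all__ = [
    "SimulationConfig",
    "ConfigError",
    "load_config",
    "dump_config",
    "config_from_dict",
    "config_to_dict",
    "apply_overrides",
    "make_fixture",
    "FIXTURE_PROFILES",
]


class ConfigError(ValueError):
    """Invalid or missing configuration key; message names the key."""


@dataclass
class SimulationConfig:
    """Complete description of one simulation condition."""

    n_loci: int = 1000
    n_generations: int = 10
    cycle_duration: float = 3600.0
    seed: int = 0
    include_cg: bool = False
    pool_policy: str = "recycle"
    initial: InitialDistributionSpec = field(default_factory=InitialDistributionSpec)
    production: ProductionSpec = field(default_factory=ProductionSpec)
    kinetics: SearchKinetics = field(default_factory=SearchKinetics.rna)

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ConfigError("simulation.n_loci must be >= 1")
        if self.n_generations < 1:
            raise ConfigError("simulation.n_generations must be >= 1")
        if self.cycle_duration <= 0:
            raise ConfigError("simulation.cycle_duration must be positive")
        if self.production.cg_coupled and not self.include_cg:
            raise ConfigError(
                "production.cg_coupled requires simulation.include_cg: true"
            )
        if self.pool_policy not in ("recycle", "carryover"):
            raise ConfigError("simulation.pool_policy must be recycle or carryover")
        if self.pool_policy == "carryover" and self.production.loading == "proportional":
            raise ConfigError(
                "simulation.pool_policy carryover requires production.loading: competitive"
            )


_SIM_KEYS = {"n_loci", "n_generations", "cycle_duration", "seed", "include_cg", "pool_policy"}


def config_to_dict(cfg: SimulationConfig) -> dict[str, Any]:
    """Serialise a config to a plain nested dict (YAML-safe types only)."""
    initial = dataclasses.asdict(cfg.initial)
    initial["anchors"] = [list(a) for a in cfg.initial.anchors]
    search = dataclasses.asdict(cfg.kinetics)
    return {
        "simulation": {
            "n_loci": cfg.n_loci,
            "n_generations": cfg.n_generations,
            "cycle_duration": cfg.cycle_duration,
            "seed": cfg.seed,
            "include_cg": cfg.include_cg,
            "pool_policy": cfg.pool_policy,
        },
        "initial": initial,
        "production": dataclasses.asdict(cfg.production),
        "search": search,
    }


def _build_section(cls, section: str, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key {section}.{sorted(unknown)[0]}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {section} section: {exc}") from exc


def config_from_dict(data: dict[str, Any]) -> SimulationConfig:
    """Build a validated :class:`SimulationConfig` from a nested dict."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    sim = dict(data.get("simulation", {}))
    unknown = set(sim) - _SIM_KEYS
    if unknown:
        raise ConfigError(f"unknown key simulation.{sorted(unknown)[0]}")
    initial_data = dict(data.get("initial", {}))
    if "anchors" in initial_data:
        initial_data["anchors"] = tuple(tuple(a) for a in initial_data["anchors"])
    production_data = dict(data.get("production", {}))
    if "production_level" not in production_data:
        raise ConfigError("missing required key production.production_level")
    search_data = dict(data.get("search", {}))
    target_type = search_data.pop("target_type", "RNA")
    extras = set(data) - {"simulation", "initial", "production", "search"}
    if extras:
        raise ConfigError(f"unknown section {sorted(extras)[0]}")
    initial = _build_section(InitialDistributionSpec, "initial", initial_data)
    production = _build_section(ProductionSpec, "production", production_data)
    try:
        kinetics = SearchKinetics.for_target(target_type, **search_data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid search section: {exc}") from exc
    try:
        return SimulationConfig(
            initial=initial, production=production, kinetics=kinetics, **sim
        )
    except TypeError as exc:
        raise ConfigError(f"invalid simulation section: {exc}") from exc


def load_config(path: str | Path) -> SimulationConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def dump_config(cfg: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def _coerce(text: str) -> Any:
    return yaml.safe_load(text)


def apply_overrides(data: dict[str, Any], overrides: list[str]) -> dict[str, Any]:
    """Apply dotted-key overrides (``section.key=value``) to a config dict."""
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in data.items()}
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override {item!r} is not of the form key=value")
        dotted, raw = item.split("=", 1)
        parts = dotted.split(".")
        node = out
        for p in parts[:-1]:
            node = node.setdefault(p, {})
            if not isinstance(node, dict):
                raise ConfigError(f"override key {dotted!r} descends into a scalar")
        node[parts[-1]] = _coerce(raw)
    return out


# ---------------------------------------------------------------------------
# test-fixture profiles: small configs that run in seconds on one CPU

FIXTURE_PROFILES = ("smoke", "decay", "calibration", "sweep_mini")


def make_fixture(profile: str) -> dict[str, Any]:
    """Return the config dict for a named fast-test profile."""
    base = {
        "simulation": {
            "n_loci": 50,
            "n_generations": 3,
            "cycle_duration": 300.0,
            "seed": 1,
            "include_cg": False,
        },
        "initial": {"mode": "quantile_matched"},
        "production": {
            "relationship": "linear",
            "production_level": 100,
            "schedule": "bursty",
        },
        "search": {"target_type": "RNA"},
    }
    if profile == "smoke":
        return base
    if profile == "decay":
        base["production"]["production_level"] = 0
        return base
    if profile == "calibration":
        base["simulation"].update(n_loci=200, n_generations=2, cycle_duration=600.0)
        base["production"]["production_level"] = 300
        return base
    if profile == "sweep_mini":
        return {
            "base": base,
            "sweep": {
                "production_levels": [100, 300],
                "saturation_points": [0.15, None],
                "schedules": ["bursty"],
                "target_types": ["RNA"],
                "relationships": ["saturated_linear"],
                "n_replicates": 3,
                "base_seed": 1,
            },
        }
    raise ConfigError(f"unknown fixture profile {profile!r}")
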