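"""Experiment configuration: a single YAML file drives the whole run.

The defaults encode the documented study conditions (cohort 2,300 over
18 months, attendance 85/90%, the Table of unit costs, screener quality
per discipline); any field may be overridden from the config file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import DEFAULT_QUALITY, PopulationParams, ScreenerProfile
from .costing import CostParams
from .scenarios import Screener
from .simulate import ComparatorParams

__all__ = ["SensitivitySweep", "ExperimentConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class SensitivitySweep:
    parameter: str  # e.g. "costs.rent_per_child_external"
    values: tuple[float, ...]


@dataclass(frozen=True)
class ExperimentConfig:
    population: PopulationParams = field(default_factory=PopulationParams)
    costs: CostParams = field(default_factory=CostParams)
    quality: dict[Screener, ScreenerProfile] = field(
        default_factory=lambda: dict(DEFAULT_QUALITY)
    )
    comparator: ComparatorParams = field(default_factory=ComparatorParams)
    n_reps: int = 100
    seed: int = 0
    n_sites: int = 7
    mode: str = "simulate"  # "simulate" | "expected"
    out_dir: str = "results"
    sensitivity: tuple[SensitivitySweep, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "expected"):
            raise ValueError(f"mode must be 'simulate' or 'expected', got {self.mode!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def _to_dict(cfg: ExperimentConfig) -> dict:
    return {
        "population": dataclasses.asdict(cfg.population),
        "costs": dataclasses.asdict(cfg.costs),
        "quality": {
            s.value: {
                "wage_per_hour": p.wage_per_hour,
                "fp_rate": p.fp_rate,
                "miss_rate": p.miss_rate,
            }
            for s, p in cfg.quality.items()
        },
        "comparator": dataclasses.asdict(cfg.comparator),
        "run": {
            "n_reps": cfg.n_reps,
            "seed": cfg.seed,
            "n_sites": cfg.n_sites,
            "mode": cfg.mode,
            "out_dir": cfg.out_dir,
        },
        "sensitivity": [
            {"parameter": s.parameter, "values": list(s.values)} for s in cfg.sensitivity
        ],
    }


def _coerce_tuples(d: dict) -> dict:
    # YAML round-trips tuples as lists; dataclass fields expect tuples.
    out = dict(d)
    for key in ("graf_mix",):
        if key in out and isinstance(out[key], list):
            out[key] = tuple(out[key])
    return out


def _from_dict(data: dict) -> ExperimentConfig:
    pop = PopulationParams(**_coerce_tuples(data.get("population", {})))
    costs = CostParams(**data.get("costs", {}))
    quality = dict(DEFAULT_QUALITY)
    for name, q in (data.get("quality") or {}).items():
        s = Screener(name)
        quality[s] = ScreenerProfile(discipline=s, **q)
    comparator = ComparatorParams(**(data.get("comparator") or {}))
    run = data.get("run", {})
    sweeps = tuple(
        SensitivitySweep(parameter=s["parameter"], values=tuple(s["values"]))
        for s in (data.get("sensitivity") or [])
    )
    return ExperimentConfig(
        population=pop,
        costs=costs,
        quality=quality,
        comparator=comparator,
        sensitivity=sweeps,
        **run,
    )


def load_config(path: str | Path | None = None, **overrides) -> ExperimentConfig:
    """Load a config file (defaults for anything unspecified).

    Keyword overrides (``seed=...``, ``n_reps=...``, ``mode=...``,
    ``out_dir=...``) take precedence over the file.
    """
    if path is None:
        cfg = ExperimentConfig()
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = _from_dict(data)
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    return cfg


def dump_config(cfg: ExperimentConfig, path: str | Path) -> None:
    """Write a config (e.g. the defaults) as YAML; round-trips exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(cfg), fh, sort_keys=False)
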