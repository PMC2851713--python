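"""Orchestration: run all 72 scenarios and write the result bundle.

Outputs (CSV unless noted):

- ``scenarios.csv`` — the enumerated scenario grid
- ``scenario_results.csv`` — one row per scenario: levels, itemised mean
  costs, counts, CE ratio with CI, quartile group
- ``quartile_frequencies.csv`` — long table (variable, level, group, count)
- ``quartile_ranges.csv`` — CE range per group
- ``extremes.csv`` — top and bottom 5 scenarios by CE
- ``comparator.csv`` — current-screening summary
- ``sensitivity_<param>.csv`` — one per configured sweep
- ``manifest.json`` — seed, mode, parameter hash, package version
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .analysis import (
    QuartileReport,
    one_way_sensitivity,
    quartile_groups,
    rank_extremes,
    results_table,
)
from .config import ExperimentConfig, _to_dict
from .scenarios import enumerate_scenarios, scenario_table
from .simulate import (
    ScenarioResult,
    expected_current,
    expected_scenario,
    simulate_current,
    simulate_scenario,
)

__all__ = ["ExperimentBundle", "run_experiment", "write_report"]

log = logging.getLogger("hipscreen")


@dataclass
class ExperimentBundle:
    """In-memory handles plus on-disk paths of one completed run."""

    config: ExperimentConfig
    out_dir: Path
    results: list[ScenarioResult]
    report: QuartileReport
    comparator: ScenarioResult
    tables: dict[str, Path]


def _comparator_frame(res: ScenarioResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strategy": "current_screening",
                "n_reps": res.n_reps,
                "mean_screened": res.mean_screened,
                "mean_detected": res.mean_detected,
                "mean_fp": res.mean_fp,
                "mean_missed": res.mean_missed,
                "mean_total_cost": res.mean_total_cost,
                "ce_ratio": res.ce_ratio,
            }
        ]
    )


def _extremes_frame(top: list[ScenarioResult], bottom: list[ScenarioResult]) -> pd.DataFrame:
    rows = []
    for kind, entries in (("most_cost_effective", top), ("least_cost_effective", bottom)):
        for rank, r in enumerate(entries, start=1):
            a, b, c, d = r.spec.level_codes
            rows.append(
                {
                    "kind": kind,
                    "rank": rank,
                    "canonical_id": r.canonical_id,
                    "machines_level": r.spec.machines_level.value,
                    "consultation": r.spec.consultation.value,
                    "screener": r.spec.screener.value,
                    "location": r.spec.location.value,
                    "level_A": a,
                    "level_B": b,
                    "level_C": c,
                    "level_D": d,
                    "ce_ratio": r.ce_ratio,
                }
            )
    return pd.DataFrame(rows)


def _param_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> ExperimentBundle:
    """Evaluate all 72 scenarios under the config and write the bundle."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs = enumerate_scenarios()

    results: list[ScenarioResult] = []
    for spec in specs:
        if config.mode == "expected":
            res = expected_scenario(
                spec, config.population, config.costs,
                profiles=config.quality, n_sites=config.n_sites,
            )
        else:
            res = simulate_scenario(
                spec, config.population, config.costs,
                n_reps=config.n_reps, seed=config.seed,
                profiles=config.quality, n_sites=config.n_sites,
            )
        log.info("scenario %2d/%d: CE = %.0f", spec.canonical_id, len(specs), res.ce_ratio)
        results.append(res)

    report = quartile_groups(results)
    top, bottom = rank_extremes(results, 5)
    if config.mode == "expected":
        comparator = expected_current(config.population, config.costs, config.comparator)
    else:
        comparator = simulate_current(
            config.population, config.costs, config.n_reps, config.seed, config.comparator
        )

    tables: dict[str, Path] = {}

    def _write(name: str, frame: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False, float_format="%.6f")
        tables[name] = path

    _write("scenarios", scenario_table(specs))
    _write("scenario_results", results_table(results, report))
    _write("quartile_frequencies", report.level_frequencies)
    _write(
        "quartile_ranges",
        pd.DataFrame(
            [
                {"group": g, "ce_min": lo, "ce_max": hi, "n": len(report.groups[g])}
                for g, (lo, hi) in report.ranges.items()
            ]
        ),
    )
    _write("extremes", _extremes_frame(top, bottom))
    _write("comparator", _comparator_frame(comparator))

    for sweep in config.sensitivity:
        frame = one_way_sensitivity(
            specs, config.population, config.costs, sweep.parameter, sweep.values,
            n_reps=0 if config.mode == "expected" else config.n_reps,
            seed=config.seed, n_sites=config.n_sites,
        )
        _write(f"sensitivity_{sweep.parameter.replace('.', '_')}", frame)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "n_reps": config.n_reps if config.mode == "simulate" else 0,
        "n_scenarios": len(results),
        "param_hash": _param_hash(config),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    tables["manifest"] = manifest_path

    return ExperimentBundle(
        config=config, out_dir=out, results=results, report=report,
        comparator=comparator, tables=tables,
    )


def write_report(bundle: ExperimentBundle) -> str:
    """Human-readable summary assembled purely from the written tables."""
    for name in ("scenario_results", "quartile_ranges", "quartile_frequencies",
                 "extremes", "comparator"):
        if name not in bundle.tables or not bundle.tables[name].exists():
            raise FileNotFoundError(f"bundle is missing table {name!r}")
    ranges = pd.read_csv(bundle.tables["quartile_ranges"])
    freq = pd.read_csv(bundle.tables["quartile_frequencies"])
    extremes = pd.read_csv(bundle.tables["extremes"])
    comparator = pd.read_csv(bundle.tables["comparator"])

    lines = ["Cost-effectiveness of ultrasound DDH screening scenarios", ""]
    lines.append("Quartile groups (cost per screen-detected child, euros):")
    for _, row in ranges.iterrows():
        lines.append(
            f"  {row['group']}: {row['ce_min']:8.0f} - {row['ce_max']:8.0f}  (n={row['n']})"
        )
    lines.append("")
    lines.append("Level frequencies per quartile group:")
    pivot = freq.pivot_table(
        index=["variable", "level"], columns="group", values="count", fill_value=0
    )
    lines.extend("  " + ln for ln in pivot.to_string().splitlines())
    lines.append("")
    for kind, title in (
        ("most_cost_effective", "Five most cost-effective scenarios:"),
        ("least_cost_effective", "Five least cost-effective scenarios:"),
    ):
        lines.append(title)
        sub = extremes[extremes["kind"] == kind]
        for _, row in sub.iterrows():
            lines.append(
                f"  #{row['rank']} (id {row['canonical_id']:2d}) "
                f"A{row['level_A']} B{row['level_B']} C{row['level_C']} D{row['level_D']}  "
                f"{row['machines_level']}/{row['consultation']}/"
                f"{row['screener']}/{row['location']}: "
                f"CE {row['ce_ratio']:.0f}"
            )
        lines.append("")
    c = comparator.iloc[0]
    lines.append(
        "Current screening (physical examination): "
        f"detected {c['mean_detected']:.1f}, false positives {c['mean_fp']:.1f}, "
        f"missed {c['mean_missed']:.1f}, CE {c['ce_ratio']:.0f}"
    )
    sens = [n for n in bundle.tables if n.startswith("sensitivity_")]
    if sens:
        lines.append("")
        lines.append("Sensitivity sweeps written: " + ", ".join(sorted(sens)))
    return "\n".join(lines) + "\n"
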