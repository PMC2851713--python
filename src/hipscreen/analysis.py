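"""Cost-effectiveness analysis over the scenario grid.

Ranks the 72 scenarios by cost per screen-detected child, partitions
them into quartile groups CE_A (most cost-effective) through CE_D
(least), tabulates how often each level of each experimental variable
occurs per group, extracts the most and least cost-effective scenarios,
and runs one-way sensitivity sweeps over any numeric parameter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import PopulationParams
from .costing import CostParams
from .scenarios import ScenarioSpec
from .simulate import ScenarioResult, expected_scenario, simulate_scenario

__all__ = [
    "GROUP_LABELS",
    "VARIABLES",
    "QuartileReport",
    "ce_ratio",
    "quartile_groups",
    "rank_extremes",
    "one_way_sensitivity",
    "results_table",
]

GROUP_LABELS = ("CE_A", "CE_B", "CE_C", "CE_D")

#: Experimental variables and how to read their level off a spec.
VARIABLES: dict[str, Callable[[ScenarioSpec], str]] = {
    "machines_level": lambda s: s.machines_level.value,
    "consultation": lambda s: s.consultation.value,
    "screener": lambda s: s.screener.value,
    "location": lambda s: s.location.value,
}


def ce_ratio(total_cost: float, n_detected: float) -> float:
    """Cost per screen-detected child: total cost / true positives."""
    if n_detected <= 0:
        raise ZeroDivisionError("CE ratio undefined: no detected children")
    return total_cost / n_detected


@dataclass
class QuartileReport:
    """Quartile partition of scenarios by CE ratio.

    ``groups`` maps CE_A..CE_D (ascending CE, i.e. most to least
    cost-effective) to the member results; ``ranges`` gives each
    group's (min, max) CE; ``level_frequencies`` is a long-format table
    (variable, level, group, count).
    """

    groups: dict[str, list[ScenarioResult]]
    ranges: dict[str, tuple[float, float]]
    level_frequencies: pd.DataFrame

    def group_of(self, canonical_id: int) -> str:
        for label, members in self.groups.items():
            if any(r.canonical_id == canonical_id for r in members):
                return label
        raise KeyError(canonical_id)


def _sorted_by_ce(results: Sequence[ScenarioResult]) -> list[ScenarioResult]:
    # Ties (improbable with floats) break by canonical id for determinism.
    return sorted(results, key=lambda r: (r.ce_ratio, r.canonical_id or 0))


def quartile_groups(results: Sequence[ScenarioResult]) -> QuartileReport:
    """Partition results into four contiguous rank-based groups.

    Group sizes are as equal as possible (18 each for the 72-scenario
    grid) and differ by at most one otherwise.
    """
    if len(results) < 4:
        raise ValueError("need at least 4 results to form quartile groups")
    ordered = _sorted_by_ce(results)
    chunks = np.array_split(np.arange(len(ordered)), 4)
    groups = {
        label: [ordered[i] for i in idx] for label, idx in zip(GROUP_LABELS, chunks)
    }
    ranges = {
        label: (members[0].ce_ratio, members[-1].ce_ratio)
        for label, members in groups.items()
    }
    rows = []
    for var, getter in VARIABLES.items():
        for label, members in groups.items():
            levels = pd.Series([getter(r.spec) for r in members])
            for level, count in levels.value_counts().sort_index().items():
                rows.append(
                    {"variable": var, "level": level, "group": label, "count": int(count)}
                )
    freq = pd.DataFrame(rows, columns=["variable", "level", "group", "count"])
    return QuartileReport(groups=groups, ranges=ranges, level_frequencies=freq)


def rank_extremes(
    results: Sequence[ScenarioResult], k: int
) -> tuple[list[ScenarioResult], list[ScenarioResult]]:
    """(k most cost-effective ascending, k least cost-effective descending)."""
    if k > len(results) // 2:
        raise ValueError(f"k={k} exceeds half the number of results")
    ordered = _sorted_by_ce(results)
    return ordered[:k], ordered[::-1][:k]


def _replace_param(
    pop: PopulationParams, costs: CostParams, param_path: str, value: float
) -> tuple[PopulationParams, CostParams]:
    try:
        prefix, name = param_path.split(".", 1)
    except ValueError:
        raise KeyError(
            f"parameter path {param_path!r} must look like 'costs.<name>' or 'pop.<name>'"
        ) from None
    if prefix == "costs":
        if not hasattr(costs, name):
            raise KeyError(f"unknown cost parameter {name!r}")
        return pop, dataclasses.replace(costs, **{name: value})
    if prefix == "pop":
        if not hasattr(pop, name):
            raise KeyError(f"unknown population parameter {name!r}")
        return dataclasses.replace(pop, **{name: value}), costs
    raise KeyError(f"unknown parameter group {prefix!r} in {param_path!r}")


def one_way_sensitivity(
    specs: Sequence[ScenarioSpec],
    pop: PopulationParams,
    costs: CostParams,
    param_path: str,
    values: Sequence[float],
    *,
    n_reps: int = 0,
    seed: int = 0,
    n_sites: int = 7,
) -> pd.DataFrame:
    """CE ratio of every scenario at each value of one parameter.

    ``param_path`` addresses a numeric field as ``"costs.<name>"`` or
    ``"pop.<name>"``. With ``n_reps=0`` the fast deterministic
    expectation oracle is used; otherwise full Monte-Carlo.
    """
    rows = []
    for value in values:
        p, c = _replace_param(pop, costs, param_path, value)
        for spec in specs:
            if n_reps == 0:
                res = expected_scenario(spec, p, c, n_sites=n_sites)
            else:
                res = simulate_scenario(spec, p, c, n_reps=n_reps, seed=seed, n_sites=n_sites)
            rows.append(
                {
                    "parameter": param_path,
                    "value": value,
                    "canonical_id": spec.canonical_id,
                    "ce_ratio": res.ce_ratio,
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["value", "canonical_id"], ignore_index=True)


def results_table(
    results: Sequence[ScenarioResult], report: QuartileReport | None = None
) -> pd.DataFrame:
    """Flat per-scenario results table (levels, costs, counts, CE, CI)."""
    rows = []
    for r in _sorted_by_ce(results):
        row = {
            "canonical_id": r.canonical_id,
            "machines_level": r.spec.machines_level.value,
            "consultation": r.spec.consultation.value,
            "screener": r.spec.screener.value,
            "location": r.spec.location.value,
            "n_reps": r.n_reps,
            "mean_screened": r.mean_screened,
            "mean_detected": r.mean_detected,
            "mean_fp": r.mean_fp,
            "mean_missed": r.mean_missed,
            "mean_total_cost": r.mean_total_cost,
            "ce_ratio": r.ce_ratio,
            "ce_ci_low": r.ce_ratio_ci[0],
            "ce_ci_high": r.ce_ratio_ci[1],
        }
        row.update({f"cost_{k}": v for k, v in r.mean_components.items()})
        if report is not None:
            row["ce_group"] = report.group_of(r.canonical_id)
        rows.append(row)
    return pd.DataFrame(rows)
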