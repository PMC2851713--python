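"""Implementation scenarios for ultrasound DDH screening.

The screening programme can be organised along four experimental
variables: how many portable ultrasound machines are purchased, whether
the exam is integrated in the regular three-month infant health care
(IHC) consultation or done in an extra consultation, which professional
discipline performs the exam, and where/when the session takes place.
The full factorial of the levels (3 x 2 x 4 x 3) yields 72 scenarios.

Each scenario implies a staffing and equipment plan: integrated
consultations with a radiographic technician or medical specialist as
screener still require an IHC physician on site for the regular
consultation, an integrated consultation screened by an IHC nurse means
the physician delegates the regular consultation to the nurse, and the
screening is organised by the IHC whenever IHC staff screen or IHC
buildings are used.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterator

import pandas as pd

__all__ = [
    "MachinesLevel",
    "Consultation",
    "Screener",
    "Location",
    "Organizer",
    "ScenarioSpec",
    "StaffingPlan",
    "N_SCENARIOS",
    "enumerate_scenarios",
    "scenario_from_id",
    "staffing_plan",
    "scenario_table",
]


class MachinesLevel(enum.Enum):
    """Number of portable ultrasound machines purchased."""

    MANY = "many"          # one machine per IHC site
    LIMITED = "limited"    # a single machine rotating between sites
    NONE = "none"          # no purchase; use machines already on site

    @property
    def code(self) -> int:
        return _CODES[MachinesLevel][self]


class Consultation(enum.Enum):
    INTEGRATED = "integrated"  # exam within the regular 3-month consultation
    EXTRA = "extra"            # separate additional consultation

    @property
    def code(self) -> int:
        return _CODES[Consultation][self]


class Screener(enum.Enum):
    IHC_PHYSICIAN = "ihc_physician"
    IHC_NURSE = "ihc_nurse"
    RADIOGRAPHIC_TECHNICIAN = "radiographic_technician"
    MEDICAL_SPECIALIST = "medical_specialist"

    @property
    def code(self) -> int:
        return _CODES[Screener][self]

    @property
    def is_ihc_employee(self) -> bool:
        return self in (Screener.IHC_PHYSICIAN, Screener.IHC_NURSE)


class Location(enum.Enum):
    IHC_DAYTIME = "ihc_daytime"
    EXTERNAL = "external"      # rented building not owned by the IHC
    IHC_EVENING = "ihc_evening"

    @property
    def code(self) -> int:
        return _CODES[Location][self]

    @property
    def is_ihc_building(self) -> bool:
        return self in (Location.IHC_DAYTIME, Location.IHC_EVENING)


# Conventional numeric level codes used in the field's scenario tables
# (variable A: 1 many / 2 limited / 3 none, etc.).
_CODES = {
    MachinesLevel: {MachinesLevel.MANY: 1, MachinesLevel.LIMITED: 2, MachinesLevel.NONE: 3},
    Consultation: {Consultation.INTEGRATED: 1, Consultation.EXTRA: 2},
    Screener: {
        Screener.IHC_PHYSICIAN: 1,
        Screener.IHC_NURSE: 2,
        Screener.RADIOGRAPHIC_TECHNICIAN: 3,
        Screener.MEDICAL_SPECIALIST: 4,
    },
    Location: {Location.IHC_DAYTIME: 1, Location.EXTERNAL: 2, Location.IHC_EVENING: 3},
}

_MACHINES = list(MachinesLevel)
_CONSULTS = list(Consultation)
_SCREENERS = list(Screener)
_LOCATIONS = list(Location)

N_SCENARIOS = len(_MACHINES) * len(_CONSULTS) * len(_SCREENERS) * len(_LOCATIONS)


class Organizer(enum.Enum):
    IHC = "ihc"
    EXTERNAL = "external"


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the 72 implementation scenarios.

    ``canonical_id`` enumerates the full factorial in mixed-radix order
    (machines-major, then consultation, then screener, then location),
    1 through 72.
    """

    machines_level: MachinesLevel
    consultation: Consultation
    screener: Screener
    location: Location

    @property
    def canonical_id(self) -> int:
        i = _MACHINES.index(self.machines_level)
        i = i * len(_CONSULTS) + _CONSULTS.index(self.consultation)
        i = i * len(_SCREENERS) + _SCREENERS.index(self.screener)
        i = i * len(_LOCATIONS) + _LOCATIONS.index(self.location)
        return i + 1

    @property
    def level_codes(self) -> tuple[int, int, int, int]:
        """(A, B, C, D) numeric level tuple."""
        return (
            self.machines_level.code,
            self.consultation.code,
            self.screener.code,
            self.location.code,
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"scenario {self.canonical_id:2d}: "
            f"{self.machines_level.value}/{self.consultation.value}/"
            f"{self.screener.value}/{self.location.value}"
        )


@dataclass(frozen=True)
class StaffingPlan:
    """Equipment and staffing consequences of a scenario."""

    machines_purchased: int
    screeners_trained: int
    physician_present_at_exam: bool
    organizer: Organizer
    nurse_delegation: bool


def enumerate_scenarios() -> list[ScenarioSpec]:
    """All 72 scenarios in canonical (mixed-radix) order."""
    return list(_iter_scenarios())


def _iter_scenarios() -> Iterator[ScenarioSpec]:
    for m in _MACHINES:
        for c in _CONSULTS:
            for s in _SCREENERS:
                for loc in _LOCATIONS:
                    yield ScenarioSpec(m, c, s, loc)


def scenario_from_id(canonical_id: int) -> ScenarioSpec:
    """Inverse of :attr:`ScenarioSpec.canonical_id`."""
    if not 1 <= canonical_id <= N_SCENARIOS:
        raise ValueError(f"canonical_id must be in 1..{N_SCENARIOS}, got {canonical_id}")
    i = canonical_id - 1
    i, l = divmod(i, len(_LOCATIONS))
    i, s = divmod(i, len(_SCREENERS))
    m, c = divmod(i, len(_CONSULTS))
    return ScenarioSpec(_MACHINES[m], _CONSULTS[c], _SCREENERS[s], _LOCATIONS[l])


def staffing_plan(spec: ScenarioSpec, n_sites: int = 7) -> StaffingPlan:
    """Derive machines, training and presence requirements for a scenario.

    Parameters
    ----------
    spec : ScenarioSpec
    n_sites : int
        Number of IHC sites served; "many machines" purchases one per
        site (default 7, the number of sites considered efficient for a
        cohort of this size).
    """
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites}")
    machines = {
        MachinesLevel.MANY: n_sites,
        MachinesLevel.LIMITED: 1,
        MachinesLevel.NONE: 0,
    }[spec.machines_level]
    # One trained screener per purchased machine; at least one screener
    # is always trained (machine-less scenarios still screen).
    trained = max(machines, 1)
    integrated = spec.consultation is Consultation.INTEGRATED
    physician_present = integrated and spec.screener in (
        Screener.RADIOGRAPHIC_TECHNICIAN,
        Screener.MEDICAL_SPECIALIST,
    )
    nurse_delegation = integrated and spec.screener is Screener.IHC_NURSE
    organizer = (
        Organizer.IHC
        if (spec.screener.is_ihc_employee or spec.location.is_ihc_building)
        else Organizer.EXTERNAL
    )
    return StaffingPlan(
        machines_purchased=machines,
        screeners_trained=trained,
        physician_present_at_exam=physician_present,
        organizer=organizer,
        nurse_delegation=nurse_delegation,
    )


def scenario_table(specs: list[ScenarioSpec] | None = None) -> pd.DataFrame:
    """Scenario enumeration as a table (one row per scenario)."""
    specs = enumerate_scenarios() if specs is None else specs
    return pd.DataFrame(
        {
            "canonical_id": [s.canonical_id for s in specs],
            "machines_level": [s.machines_level.value for s in specs],
            "consultation": [s.consultation.value for s in specs],
            "screener": [s.screener.value for s in specs],
            "location": [s.location.value for s in specs],
        }
    )
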