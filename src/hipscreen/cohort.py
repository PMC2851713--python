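"""Synthetic screening cohorts.

Emulates the population entering three-month ultrasound hip screening:
2,300 children arriving over 18 months, a latent Graf hip status
(healthy, or a treatable type 2b/c, D, or 3/4 hip), urban or rural
residence driving attendance behaviour, and a travel distance of 4-7 km
to the infant health care centre (IHC).

The cohort is the *post-exclusion* screening population: children who
were already referred and treated in their first months of life (before
the three-month screen) are accounted for as a small pre-screening
stage — expected counts of about 0.31% treated and a further 0.30%
referred-but-not-treated per cohort — that contributes programme costs
but does not deplete the cohort, so the prevalence among screened
children stays at the configured value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scenarios import Screener

__all__ = [
    "Region",
    "HipStatus",
    "PopulationParams",
    "ScreenerProfile",
    "Cohort",
    "PrescreenSummary",
    "DEFAULT_QUALITY",
    "generate_cohort",
    "conditional_rates",
]


class Region(enum.IntEnum):
    URBAN = 0
    RURAL = 1


class HipStatus(enum.IntEnum):
    """Latent hip classification; non-healthy types all receive treatment."""

    HEALTHY = 0
    TYPE_2BC = 1
    TYPE_D = 2
    TYPE_34 = 3


AFFECTED_STATUSES = (HipStatus.TYPE_2BC, HipStatus.TYPE_D, HipStatus.TYPE_34)


@dataclass(frozen=True)
class PopulationParams:
    """Cohort structure and attendance behaviour.

    ``prevalence`` is the proportion of screened children with a
    treatable hip (default 3.8% = 3.2% true positives + 0.6% missed).
    ``graf_mix`` gives the relative weights of types 2b/c, D and 3/4;
    the printed per-type rates (1.4, 1.5, 0.5%) sum to 3.4%, so the mix
    is renormalised to the configured prevalence.
    """

    cohort_size: int = 2300
    horizon_months: float = 18.0
    prevalence: float = 0.038
    graf_mix: tuple[float, float, float] = (0.014, 0.015, 0.005)
    urban_share: float = 2.0 / 3.0
    attendance_urban: float = 0.85
    attendance_rural: float = 0.90
    reattendance_urban: float = 0.80
    reattendance_rural: float = 0.90
    prescreen_referral: float = 0.0061
    prescreen_treated: float = 0.0031
    distance_km_min: float = 4.0
    distance_km_max: float = 7.0

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        props = {
            "prevalence": self.prevalence,
            "urban_share": self.urban_share,
            "attendance_urban": self.attendance_urban,
            "attendance_rural": self.attendance_rural,
            "reattendance_urban": self.reattendance_urban,
            "reattendance_rural": self.reattendance_rural,
            "prescreen_referral": self.prescreen_referral,
            "prescreen_treated": self.prescreen_treated,
        }
        for name, p in props.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.prescreen_treated > self.prescreen_referral:
            raise ValueError("prescreen_treated cannot exceed prescreen_referral")
        if any(w < 0 for w in self.graf_mix) or sum(self.graf_mix) <= 0 < self.prevalence:
            raise ValueError("graf_mix weights must be non-negative with positive sum")
        if not 0 <= self.distance_km_min <= self.distance_km_max:
            raise ValueError("invalid distance range")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be positive")

    @property
    def status_probs(self) -> np.ndarray:
        """P(status) over (HEALTHY, TYPE_2BC, TYPE_D, TYPE_34)."""
        if self.prevalence == 0:
            return np.array([1.0, 0.0, 0.0, 0.0])
        w = np.asarray(self.graf_mix, dtype=float)
        w = w / w.sum() * self.prevalence
        return np.concatenate([[1.0 - self.prevalence], w])

    @property
    def graf_mix_conditional(self) -> np.ndarray:
        """Graf-type distribution conditional on being affected."""
        w = np.asarray(self.graf_mix, dtype=float)
        return w / w.sum()

    def attendance(self, region: Region) -> float:
        return self.attendance_urban if region == Region.URBAN else self.attendance_rural

    def reattendance(self, region: Region) -> float:
        return self.reattendance_urban if region == Region.URBAN else self.reattendance_rural

    def p_screened(self, region: Region) -> float:
        """Overall screening probability: first invitation or after reminder."""
        a, r = self.attendance(region), self.reattendance(region)
        return a + (1.0 - a) * r

    @property
    def p_screened_marginal(self) -> float:
        return self.urban_share * self.p_screened(Region.URBAN) + (
            1.0 - self.urban_share
        ) * self.p_screened(Region.RURAL)


@dataclass(frozen=True)
class ScreenerProfile:
    """Operating characteristics and wage of one screener discipline.

    ``fp_rate`` and ``miss_rate`` are proportions of *all screened
    children* (not conditional rates); see :func:`conditional_rates`.
    """

    discipline: Screener
    wage_per_hour: float
    fp_rate: float
    miss_rate: float

    def __post_init__(self) -> None:
        if self.wage_per_hour <= 0:
            raise ValueError("wage_per_hour must be positive")
        if not (0 <= self.fp_rate <= 1 and 0 <= self.miss_rate <= 1):
            raise ValueError("rates must be proportions")
        if self.fp_rate + self.miss_rate >= 1:
            raise ValueError("fp_rate + miss_rate must be < 1")


#: Screener quality (proportions of all screened children) and wages.
DEFAULT_QUALITY: dict[Screener, ScreenerProfile] = {
    Screener.IHC_PHYSICIAN: ScreenerProfile(Screener.IHC_PHYSICIAN, 75.0, 0.014, 0.006),
    Screener.IHC_NURSE: ScreenerProfile(Screener.IHC_NURSE, 42.0, 0.015, 0.007),
    Screener.RADIOGRAPHIC_TECHNICIAN: ScreenerProfile(
        Screener.RADIOGRAPHIC_TECHNICIAN, 70.0, 0.013, 0.006
    ),
    Screener.MEDICAL_SPECIALIST: ScreenerProfile(Screener.MEDICAL_SPECIALIST, 106.0, 0.006, 0.003),
}


@dataclass(frozen=True)
class PrescreenSummary:
    """Children handled before the three-month screen.

    ``n_treated`` were detected and treated at the first IHC
    consultations (true cases outside the screening cohort);
    ``n_referred_untreated`` were referred but DDH was refuted, costing
    one hospital visit each.
    """

    n_treated: int
    n_referred_untreated: int


@dataclass
class Cohort:
    """A realised synthetic cohort (parallel arrays, one entry per child)."""

    child_id: np.ndarray
    region: np.ndarray          # Region codes (int8)
    true_status: np.ndarray     # HipStatus codes (int8)
    distance_km_ihc: np.ndarray
    arrival_month: np.ndarray
    prescreen: PrescreenSummary
    params: PopulationParams = field(repr=False)

    @property
    def n(self) -> int:
        return self.child_id.size

    @property
    def affected(self) -> np.ndarray:
        return self.true_status != HipStatus.HEALTHY

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "child_id": self.child_id,
                "region": pd.Categorical.from_codes(self.region, [r.name.lower() for r in Region]),
                "true_status": pd.Categorical.from_codes(
                    self.true_status, [s.name.lower() for s in HipStatus]
                ),
                "distance_km_ihc": self.distance_km_ihc,
                "arrival_month": self.arrival_month,
            }
        )


def generate_cohort(pop: PopulationParams, rng: np.random.Generator | int) -> Cohort:
    """Draw one cohort.

    Residence is Bernoulli(urban_share), latent hip status categorical
    with the renormalised Graf mix, travel distance uniform on the
    configured range, arrival uniform over the horizon. The prescreen
    stage draws Binomial counts of earlier-treated and
    referred-but-untreated children. Deterministic given the generator
    state (or integer seed).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = pop.cohort_size
    region = np.where(rng.random(n) < pop.urban_share, Region.URBAN, Region.RURAL).astype(np.int8)
    status = rng.choice(len(HipStatus), size=n, p=pop.status_probs).astype(np.int8)
    distance = rng.uniform(pop.distance_km_min, pop.distance_km_max, size=n)
    arrival = rng.uniform(0.0, pop.horizon_months, size=n)
    n_treated = int(rng.binomial(n, pop.prescreen_treated))
    n_ref_untreated = int(rng.binomial(n, pop.prescreen_referral - pop.prescreen_treated))
    return Cohort(
        child_id=np.arange(n),
        region=region,
        true_status=status,
        distance_km_ihc=distance,
        arrival_month=arrival,
        prescreen=PrescreenSummary(n_treated, n_ref_untreated),
        params=pop,
    )


def conditional_rates(profile: ScreenerProfile, prevalence: float) -> tuple[float, float]:
    """Convert whole-cohort error proportions to conditional probabilities.

    Returns ``(miss_given_affected, fp_given_healthy)`` where
    ``miss_given_affected = miss_rate / prevalence`` and
    ``fp_given_healthy = fp_rate / (1 - prevalence)``.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    if profile.miss_rate > prevalence:
        raise ValueError(
            f"miss_rate {profile.miss_rate} exceeds prevalence {prevalence}: "
            "more misses than affected children"
        )
    if profile.fp_rate > 1.0 - prevalence:
        raise ValueError("fp_rate exceeds the healthy proportion")
    return profile.miss_rate / prevalence, profile.fp_rate / (1.0 - prevalence)
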