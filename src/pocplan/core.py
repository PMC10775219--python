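"""Domain types and deterministic turnaround-time building blocks.

A county viral-load (VL) testing system is described by clinics
(:class:`Facility`) that collect samples, testing sites
(:class:`TestingSite`: central labs and point-of-care hubs) that process
them, and a travel-distance matrix between the two.  Turnaround time per
sample decomposes into three parts, all handled in **minutes** internally:

* batching delay at the clinic (set by dispatch frequency),
* transport time clinic -> testing site,
* waiting + service time at the testing site (see :mod:`pocplan.queueing`).

Service rates are stored per *working day*; one working day is
``workday_hours`` hours (7 by default, 20 workdays per month).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import pandas as pd

__all__ = [
    "ValidationError",
    "TRANSPORT_SPEEDS_KMH",
    "CONDITION_COEFFS",
    "BATCHING_MODES",
    "DEFAULT_WORKDAY_HOURS",
    "DEFAULT_WORKDAYS_PER_MONTH",
    "Facility",
    "TestingSite",
    "TransportParams",
    "BatchingPolicy",
    "ProblemInstance",
    "estimate_annual_demand",
    "estimate_daily_demand",
    "expected_batching_delay",
    "transport_time",
]


class ValidationError(ValueError):
    """Raised when an input violates a model invariant."""


#: Average travel speed by mode, km/h.
TRANSPORT_SPEEDS_KMH = {"walk": 5.0, "bike": 20.0, "motorbike": 40.0, "car": 50.0}

#: Road / weather condition multipliers on travel time.
CONDITION_COEFFS = {"good": 0.8, "average": 1.0, "bad": 1.2}

#: Sample dispatch frequencies, slowest-delay order.
BATCHING_MODES = ("daily", "twice_weekly", "once_weekly")

DEFAULT_WORKDAY_HOURS = 7.0
DEFAULT_WORKDAYS_PER_MONTH = 20

MINUTES_PER_HOUR = 60.0


# ---------------------------------------------------------------------------
# demand estimation
# ---------------------------------------------------------------------------

def estimate_annual_demand(child_volume: float, adult_volume: float) -> float:
    """Expected VL tests per year for a clinic.

    Children are tested twice a year; adults average 1.08 tests per year
    (6-monthly in the first treatment year, annually thereafter), so

    ``annual = 2 * child_volume + 1.08 * adult_volume``.
    """
    if child_volume < 0 or adult_volume < 0:
        raise ValidationError("client volumes must be non-negative")
    return 2.0 * child_volume + 1.08 * adult_volume


def estimate_daily_demand(
    annual_demand: float, workdays_per_month: int = DEFAULT_WORKDAYS_PER_MONTH
) -> float:
    """Samples per working day, assuming ``workdays_per_month`` workdays."""
    if annual_demand < 0:
        raise ValidationError("annual demand must be non-negative")
    if workdays_per_month <= 0:
        raise ValidationError("workdays_per_month must be positive")
    return annual_demand / (12.0 * workdays_per_month)


# ---------------------------------------------------------------------------
# batching delay
# ---------------------------------------------------------------------------

def expected_batching_delay(
    mode: str, workday_hours: float = DEFAULT_WORKDAY_HOURS
) -> float:
    """Expected delay (minutes) a sample spends at the clinic before dispatch.

    With an ``h``-hour working day and 24-hour calendar days:

    * ``daily``        -> h / 2                (half a working day)
    * ``twice_weekly`` -> 24 + h               (one calendar day + one workday)
    * ``once_weekly``  -> (4 * 24 + h) / 2     (half the working week span)

    At the 7-hour default these are 210, 1860 and 3090 minutes.
    """
    if workday_hours <= 0:
        raise ValidationError("workday_hours must be positive")
    if mode == "daily":
        hours = workday_hours / 2.0
    elif mode == "twice_weekly":
        hours = 24.0 + workday_hours
    elif mode == "once_weekly":
        hours = (4.0 * 24.0 + workday_hours) / 2.0
    else:
        raise ValidationError(
            f"unknown batching mode {mode!r}; expected one of {BATCHING_MODES}"
        )
    return hours * MINUTES_PER_HOUR


# ---------------------------------------------------------------------------
# transport time
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransportParams:
    """One transport mode with road/weather adjustment, applied system-wide."""

    mode: str = "motorbike"
    speed_kmh: Optional[float] = None  # default looked up from mode
    road_coeff: float = 1.0
    weather_coeff: float = 1.0

    def __post_init__(self) -> None:
        if self.speed_kmh is None:
            if self.mode not in TRANSPORT_SPEEDS_KMH:
                raise ValidationError(
                    f"unknown transport mode {self.mode!r} and no speed given"
                )
            object.__setattr__(self, "speed_kmh", TRANSPORT_SPEEDS_KMH[self.mode])
        if self.speed_kmh <= 0:
            raise ValidationError("transport speed must be positive")
        if self.road_coeff <= 0 or self.weather_coeff <= 0:
            raise ValidationError("condition coefficients must be positive")


def transport_time(distance_km: float, transport: TransportParams) -> float:
    """One-way travel time in minutes over ``distance_km``."""
    if distance_km < 0:
        raise ValidationError("distance must be non-negative")
    hours = distance_km / transport.speed_kmh
    return hours * transport.road_coeff * transport.weather_coeff * MINUTES_PER_HOUR


@dataclass(frozen=True)
class BatchingPolicy:
    """Dispatch frequency for samples collected at clinics."""

    mode: str = "twice_weekly"
    workday_hours: float = DEFAULT_WORKDAY_HOURS

    def __post_init__(self) -> None:
        # validates the mode eagerly
        expected_batching_delay(self.mode, self.workday_hours)

    @property
    def expected_delay_min(self) -> float:
        return expected_batching_delay(self.mode, self.workday_hours)


# ---------------------------------------------------------------------------
# facilities and testing sites
# ---------------------------------------------------------------------------

@dataclass
class Facility:
    """A clinic that collects VL samples and refers them for testing."""

    id: str
    name: str
    level: int  # Kenya Package for Health facility level, 1..5
    sub_county: str
    lat: float
    lon: float
    annual_child_volume: float
    annual_adult_volume: float
    current_site_id: str  # lab used under the existing referral network
    workdays_per_month: int = DEFAULT_WORKDAYS_PER_MONTH
    daily_demand: float = field(init=False)

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3, 4, 5):
            raise ValidationError(f"facility {self.id}: level must be in 1..5")
        annual = estimate_annual_demand(
            self.annual_child_volume, self.annual_adult_volume
        )
        self.daily_demand = estimate_daily_demand(annual, self.workdays_per_month)


SITE_KINDS = ("central_lab", "existing_hub", "candidate_hub")


@dataclass
class TestingSite:
    """A central lab or a point-of-care hub (existing or candidate).

    Central labs run a two-stage process (sample data entry, then machine
    testing) and also receive a background stream of samples from outside
    the county; ``kisumu_fraction`` is the in-county share of their total
    intake.  Hubs run a single M/M/s stage whose per-machine rate is scaled
    by ``vl_fraction``, the share of machine time dedicated to VL testing.
    """

    __test__ = False  # not a test class, despite the Test* name

    id: str
    name: str
    kind: str
    sub_county: str
    lat: float
    lon: float
    machine_service_rate: float  # samples / working day / machine
    n_machines: int
    n_entry_servers: int = 0  # central labs only
    entry_service_rate: float = 0.0  # per server, samples / working day
    kisumu_fraction: float = 1.0  # central labs only
    vl_fraction: float = 1.0  # hubs only
    fixed_open: bool = True
    level: Optional[int] = None  # hubs sit inside a facility with a level

    def __post_init__(self) -> None:
        if self.kind not in SITE_KINDS:
            raise ValidationError(f"site {self.id}: unknown kind {self.kind!r}")
        if self.machine_service_rate <= 0:
            raise ValidationError(f"site {self.id}: machine_service_rate must be > 0")
        if self.n_machines < 1:
            raise ValidationError(f"site {self.id}: n_machines must be >= 1")
        if self.is_central_lab:
            if self.n_entry_servers < 1 or self.entry_service_rate <= 0:
                raise ValidationError(
                    f"central lab {self.id}: entry stage needs servers and a rate"
                )
            if not (0 < self.kisumu_fraction <= 1):
                raise ValidationError(
                    f"central lab {self.id}: kisumu_fraction must be in (0, 1]"
                )
            if not self.fixed_open:
                raise ValidationError(f"central lab {self.id} must be fixed_open")
        else:
            if not (0 < self.vl_fraction <= 1):
                raise ValidationError(
                    f"hub {self.id}: vl_fraction must be in (0, 1]"
                )
            if self.kind == "existing_hub" and not self.fixed_open:
                raise ValidationError(f"existing hub {self.id} must be fixed_open")
            if self.kind == "candidate_hub" and self.fixed_open:
                raise ValidationError(f"candidate hub {self.id} must not be fixed_open")

    @property
    def is_central_lab(self) -> bool:
        return self.kind == "central_lab"

    @property
    def is_hub(self) -> bool:
        return self.kind in ("existing_hub", "candidate_hub")


# ---------------------------------------------------------------------------
# problem instance
# ---------------------------------------------------------------------------

@dataclass
class ProblemInstance:
    """A complete planning problem: clinics, sites, distances and settings.

    ``distance_km`` is a facility x site DataFrame (rows indexed by facility
    id, columns by site id).  ``travel_time_min``, when given, overrides the
    speed-based transport-time computation for the pairs it covers.
    """

    facilities: List[Facility]
    sites: List[TestingSite]
    distance_km: pd.DataFrame
    transport: TransportParams = field(default_factory=TransportParams)
    batching: BatchingPolicy = field(default_factory=BatchingPolicy)
    n_added_hubs: int = 0
    fairness: bool = False
    utilization_cap: float = 0.9
    workday_hours: float = DEFAULT_WORKDAY_HOURS
    workdays_per_month: int = DEFAULT_WORKDAYS_PER_MONTH
    travel_time_min: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ------------------------------------------------------------

    @property
    def site_by_id(self) -> Dict[str, TestingSite]:
        return {s.id: s for s in self.sites}

    @property
    def facility_by_id(self) -> Dict[str, Facility]:
        return {f.id: f for f in self.facilities}

    @property
    def central_labs(self) -> List[TestingSite]:
        return [s for s in self.sites if s.kind == "central_lab"]

    @property
    def existing_hubs(self) -> List[TestingSite]:
        return [s for s in self.sites if s.kind == "existing_hub"]

    @property
    def candidate_hubs(self) -> List[TestingSite]:
        return [s for s in self.sites if s.kind == "candidate_hub"]

    @property
    def sub_counties(self) -> List[str]:
        return sorted({f.sub_county for f in self.facilities})

    # -- derived quantities --------------------------------------------------

    def transport_minutes(self, facility_id: str, site_id: str) -> float:
        """Transport time for one referral, honouring the travel-time override."""
        if self.travel_time_min is not None:
            try:
                override = self.travel_time_min.at[facility_id, site_id]
            except KeyError:
                override = None
            if override is not None and not (
                isinstance(override, float) and math.isnan(override)
            ):
                return float(override)
        return transport_time(
            float(self.distance_km.at[facility_id, site_id]), self.transport
        )

    def total_daily_demand(self) -> float:
        return sum(f.daily_demand for f in self.facilities)

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        fac_ids = [f.id for f in self.facilities]
        site_ids = [s.id for s in self.sites]
        if len(set(fac_ids)) != len(fac_ids):
            raise ValidationError("duplicate facility ids")
        if len(set(site_ids)) != len(site_ids):
            raise ValidationError("duplicate site ids")
        if not (0 < self.utilization_cap <= 1):
            raise ValidationError("utilization_cap must be in (0, 1]")
        if self.n_added_hubs < 0:
            raise ValidationError("n_added_hubs must be non-negative")
        if self.n_added_hubs > len(self.candidate_hubs):
            raise ValidationError(
                f"n_added_hubs={self.n_added_hubs} exceeds the "
                f"{len(self.candidate_hubs)} candidate hubs"
            )
        lab_ids = {s.id for s in self.central_labs}
        for f in self.facilities:
            if f.current_site_id not in lab_ids:
                raise ValidationError(
                    f"facility {f.id}: current_site_id {f.current_site_id!r} "
                    "is not a central lab"
                )
            if f.workdays_per_month != self.workdays_per_month:
                # keep the cached daily demand consistent with instance settings
                f.workdays_per_month = self.workdays_per_month
                f.__post_init__()
        missing_rows = set(fac_ids) - set(self.distance_km.index)
        missing_cols = set(site_ids) - set(self.distance_km.columns)
        if missing_rows or missing_cols:
            raise ValidationError(
                f"distance matrix incomplete: missing rows {sorted(missing_rows)}, "
                f"columns {sorted(missing_cols)}"
            )
        block = self.distance_km.loc[fac_ids, site_ids]
        if block.isna().any().any() or (block < 0).any().any():
            raise ValidationError("distance matrix has missing or negative entries")

    def replace(self, **kwargs) -> "ProblemInstance":
        """Return a copy of the instance with some settings replaced."""
        return replace(self, **kwargs)
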