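"""Seeded generator of county-like planning instances.

The generator emulates the structure of a western-Kenya county VL testing
system so that every stage of the package is exercisable without any
external download:

* ~146 clinics clustered into sub-counties inside a bounding box, with
  facility levels 1-5 and right-skewed daily demand in [0, 37];
* one in-county reference lab at the lake-shore corner of the county plus
  two distant labs 50-150 km away, with the two-stage queue parameters and
  in-county sample shares (24%/13%/5%) of the real system;
* seven existing POC hubs hosted at the county's largest hospitals with
  machine counts {4,2,1,1,1,1,1}, and twelve level-3+ candidate hub sites
  covering every sub-county (so the fairness constraint is feasible);
* road distances approximated as great-circle x a circuity factor.

Demand is calibrated per current-lab group so that the in-county lab runs
essentially at saturation under the existing network (its real-world
regime: county demand roughly equals the lab's adjusted entry capacity)
while the distant labs carry mostly out-of-county background.  The
existing referral network misroutes ~20% of clinics to a distant lab.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    BatchingPolicy,
    Facility,
    ProblemInstance,
    TestingSite,
    TransportParams,
)

__all__ = [
    "GeneratorConfig",
    "GenerationError",
    "generate_instance",
    "make_fixture_small",
    "haversine_km",
]

EARTH_RADIUS_KM = 6371.0088


class GenerationError(RuntimeError):
    """The configuration cannot produce a feasible instance."""


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km between two WGS84 points."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


@dataclass(frozen=True)
class GeneratorConfig:
    """Dials of the synthetic county; defaults emulate the study county."""

    seed: int  # mandatory for reproducibility
    n_facilities: int = 146
    n_subcounties: int = 7
    n_central_labs: int = 3
    n_existing_hubs: int = 7
    existing_hub_machines: Tuple[int, ...] = (4, 2, 1, 1, 1, 1, 1)
    n_candidate_hubs: int = 12
    candidate_hub_machines: int = 2
    demand_max_daily: float = 37.0
    level_distribution: Tuple[float, ...] = (0.15, 0.35, 0.30, 0.15, 0.05)
    # lon_min, lat_min, lon_max, lat_max (degrees); Winam-gulf-like county
    bbox: Tuple[float, float, float, float] = (34.35, -0.55, 35.20, 0.15)
    circuity_factor: float = 1.3
    misassignment_rate: float = 0.2
    kisumu_fractions: Tuple[float, ...] = (0.24, 0.13, 0.05)
    # entry-stage utilization of each lab under the existing network; the
    # in-county lab runs near saturation, the distant labs carry mostly
    # out-of-county work on top of a small in-county share
    lab_utilization_targets: Tuple[float, ...] = (0.9975, 0.10, 0.12)
    remote_lab_km: Tuple[float, float] = (90.0, 130.0)
    # e-folding distance (km from the in-county lab) of the urban demand
    # gradient: client volume concentrates in the city, periphery is sparse
    demand_decay_km: float = 12.0
    n_entry_servers: int = 2
    entry_service_rate: float = 710.0
    lab_machine_rate: float = 1500.0
    poc_machine_rate: float = 12.0
    host_fill_fraction: float = 0.88  # hub-host demand as share of raw capacity

    def __post_init__(self) -> None:
        if self.n_central_labs != len(self.kisumu_fractions) or (
            self.n_central_labs != len(self.lab_utilization_targets)
        ):
            raise GenerationError("one fraction and one target per central lab")
        if len(self.existing_hub_machines) != self.n_existing_hubs:
            raise GenerationError("one machine count per existing hub")
        if min(
            self.n_facilities,
            self.n_subcounties,
            self.n_central_labs,
            self.n_existing_hubs,
            self.n_candidate_hubs,
        ) <= 0:
            raise GenerationError("all counts must be positive")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _scale_with_caps(
    weights: np.ndarray, target: float, caps: np.ndarray, iters: int = 12
) -> np.ndarray:
    """Scale ``weights`` to sum to ``target`` while respecting per-item caps."""
    d = weights.astype(float).copy()
    if d.sum() <= 0:
        raise GenerationError("cannot scale a zero-demand group")
    clamped = np.zeros(len(d), dtype=bool)
    for _ in range(iters):
        free = ~clamped
        remaining = target - d[clamped].sum()
        if remaining < 0 or not free.any() or d[free].sum() == 0:
            break
        d[free] *= remaining / d[free].sum()
        over = free & (d > caps)
        if not over.any():
            break
        d[over] = caps[over]
        clamped |= over
    return d


def _volumes_from_daily(
    daily: float, workdays_per_month: int = 20, child_share: float = 0.1
) -> Tuple[int, int]:
    """Integer child/adult annual volumes whose derived demand ~= ``daily``.

    Children are ~10% of adults, so annual = (2 * 0.1 + 1.08) * adult.
    """
    annual = daily * 12 * workdays_per_month
    adult = int(round(annual / (2 * child_share + 1.08)))
    child = int(round(child_share * adult))
    return child, adult


def _derived_daily(child: int, adult: int, workdays_per_month: int = 20) -> float:
    return (2 * child + 1.08 * adult) / (12 * workdays_per_month)


def _offset_latlon(lat: float, lon: float, km: float, bearing_deg: float):
    b = math.radians(bearing_deg)
    dlat = km * math.cos(b) / 110.574
    dlon = km * math.sin(b) / (111.320 * math.cos(math.radians(lat)))
    return lat + dlat, lon + dlon


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_instance(config: GeneratorConfig) -> ProblemInstance:
    """Draw a complete, validated, feasibility-checked ProblemInstance."""
    rng = np.random.default_rng(config.seed)
    lon_min, lat_min, lon_max, lat_max = config.bbox
    nf = config.n_facilities

    # sub-county centres: jittered spread over the box
    centres = np.column_stack(
        [
            rng.uniform(lat_min + 0.05, lat_max - 0.05, config.n_subcounties),
            rng.uniform(lon_min + 0.08, lon_max - 0.08, config.n_subcounties),
        ]
    )
    sub_names = [f"SC{k + 1}" for k in range(config.n_subcounties)]
    sc_idx = np.sort(rng.integers(0, config.n_subcounties, nf))
    lat = np.clip(centres[sc_idx, 0] + rng.normal(0, 0.06, nf), lat_min, lat_max)
    lon = np.clip(centres[sc_idx, 1] + rng.normal(0, 0.06, nf), lon_min, lon_max)
    levels = 1 + rng.choice(5, size=nf, p=np.asarray(config.level_distribution))

    # central labs: the in-county lab sits in the county capital — the
    # sub-county closest to the lake-shore (NW) corner — and two distant
    corner = (lat_min + 0.85 * (lat_max - lat_min),
              lon_min + 0.10 * (lon_max - lon_min))
    city = int(np.argmin([
        haversine_km(c[0], c[1], corner[0], corner[1]) for c in centres
    ]))
    lab1_lat, lab1_lon = float(centres[city, 0]), float(centres[city, 1])
    remote = []
    for bearing in (35.0, 140.0):  # NE and SE of the county
        km = rng.uniform(*config.remote_lab_km)
        remote.append(_offset_latlon(lab1_lat, lab1_lon, km, bearing))
    lab_coords = [(lab1_lat, lab1_lon)] + remote
    lab_ids = [f"L{j + 1}" for j in range(config.n_central_labs)]

    # raw right-skewed demand weights, ~5% zero-demand clinics, with an
    # urban gradient: volume concentrates around the in-county lab's city
    raw = rng.lognormal(mean=0.2, sigma=1.1, size=nf)
    raw[rng.random(nf) < 0.05] = 0.0
    d_city = np.array(
        [haversine_km(lat[i], lon[i], lab1_lat, lab1_lon) for i in range(nf)]
    )
    raw *= np.exp(-d_city / config.demand_decay_km)

    # hub hosts: the county's largest facilities, routed to the in-county lab
    host_order = np.argsort(-raw)
    hosts = list(host_order[: config.n_existing_hubs])
    machine_by_host = dict(zip(hosts, config.existing_hub_machines))
    for rank, i in enumerate(hosts):
        levels[i] = 5 if rank == 0 else 4

    # existing referral network: nearest lab, with ~20% of clinics misrouted
    # to a distant lab (weighted toward the nearer of the two).  Misrouting
    # afflicts the smaller clinics: high-volume hospitals have established
    # courier relationships with the in-county reference lab.
    current = np.zeros(nf, dtype=int)  # nearest is the in-county lab for all
    non_hosts = [i for i in range(nf) if i not in hosts]
    small = [i for i in non_hosts if raw[i] <= np.quantile(raw[non_hosts], 0.6)]
    n_mis = int(round(config.misassignment_rate * nf))
    mis = rng.choice(small, size=min(n_mis, len(small)), replace=False)
    current[mis] = rng.choice(
        np.arange(1, config.n_central_labs),
        size=len(mis),
        p=_remote_weights(config.n_central_labs),
    )
    for j in range(1, config.n_central_labs):
        if not (current == j).any():  # every lab needs an in-county stream
            current[rng.choice(mis if len(mis) else non_hosts)] = j

    # per-lab in-county demand targets from the utilization calibration
    entry_capacity = config.n_entry_servers * config.entry_service_rate
    bottleneck = min(entry_capacity, config.lab_machine_rate)
    targets = [
        u * f * bottleneck
        for u, f in zip(config.lab_utilization_targets, config.kisumu_fractions)
    ]

    daily = raw.copy()
    caps = np.full(nf, config.demand_max_daily)
    # pin hub hosts near (below) their own hub's VL capacity
    for i, m in machine_by_host.items():
        daily[i] = min(
            config.host_fill_fraction * m * config.poc_machine_rate,
            config.demand_max_daily,
        )
    # the single largest machine-less clinic spans the demand range
    top_free = next(i for i in host_order if i not in hosts and current[i] == 0)
    daily[top_free] = config.demand_max_daily
    pinned = set(hosts) | {top_free}
    for j in range(config.n_central_labs):
        group = [i for i in range(nf) if current[i] == j and i not in pinned]
        pinned_sum = sum(daily[i] for i in pinned if current[i] == j)
        sub = np.array(group, dtype=int)
        daily[sub] = _scale_with_caps(
            raw[sub] + 1e-6, targets[j] - pinned_sum, caps[sub]
        )

    # integer client volumes; then re-derive demand from the volumes
    child = np.zeros(nf, dtype=int)
    adult = np.zeros(nf, dtype=int)
    for i in range(nf):
        child[i], adult[i] = _volumes_from_daily(daily[i])
    for i in range(nf):  # integer rounding must not breach the demand cap
        while adult[i] > 0 and _derived_daily(child[i], adult[i]) > (
            config.demand_max_daily
        ):
            adult[i] -= 1
    derived = np.array([_derived_daily(child[i], adult[i]) for i in range(nf)])
    # absorb integer-rounding drift so the in-county lab lands exactly on
    # its near-saturation target (it must stay strictly stable); a mid-size
    # unpinned clinic takes the +/- few samples/day correction
    drift = derived[current == 0].sum() - targets[0]
    buffer_i = max(
        (i for i in range(nf) if current[i] == 0 and i not in pinned),
        key=lambda i: derived[i],
    )
    adult[buffer_i] -= int(round(drift * 240 / 1.08))
    adult[buffer_i] = max(adult[buffer_i], 0)
    derived[buffer_i] = _derived_daily(child[buffer_i], adult[buffer_i])
    if derived[buffer_i] > config.demand_max_daily:
        raise GenerationError("rounding correction exceeded the demand cap")

    # candidate hubs: coverage-driven siting in underserved areas — one
    # level-3+ clinic per sub-county first, then by distance from the
    # existing testing sites
    existing_coords = [(lab1_lat, lab1_lon)] + [
        (float(lat[i]), float(lon[i])) for i in hosts
    ]
    cand_hosts = _pick_candidates(
        config, levels, derived, sc_idx, hosts, lat, lon, existing_coords
    )

    facilities = [
        Facility(
            id=f"F{i + 1:03d}",
            name=f"Clinic {i + 1}",
            level=int(levels[i]),
            sub_county=sub_names[sc_idx[i]],
            lat=float(lat[i]),
            lon=float(lon[i]),
            annual_child_volume=int(child[i]),
            annual_adult_volume=int(adult[i]),
            current_site_id=lab_ids[current[i]],
        )
        for i in range(nf)
    ]

    sites: List[TestingSite] = []
    for j, lid in enumerate(lab_ids):
        sites.append(
            TestingSite(
                id=lid,
                name=f"Central lab {j + 1}",
                kind="central_lab",
                sub_county=sub_names[sc_idx[0]] if j == 0 else "out_of_county",
                lat=lab_coords[j][0],
                lon=lab_coords[j][1],
                machine_service_rate=config.lab_machine_rate,
                n_machines=1,
                n_entry_servers=config.n_entry_servers,
                entry_service_rate=config.entry_service_rate,
                kisumu_fraction=config.kisumu_fractions[j],
                fixed_open=True,
            )
        )
    for rank, i in enumerate(hosts):
        sites.append(
            TestingSite(
                id=f"H{rank + 1}",
                name=f"Hub at {facilities[i].name}",
                kind="existing_hub",
                sub_county=facilities[i].sub_county,
                lat=facilities[i].lat,
                lon=facilities[i].lon,
                machine_service_rate=config.poc_machine_rate,
                n_machines=int(machine_by_host[i]),
                vl_fraction=1.0,
                fixed_open=True,
                level=facilities[i].level,
            )
        )
    for k, i in enumerate(cand_hosts):
        sites.append(
            TestingSite(
                id=f"C{k + 1:02d}",
                name=f"Candidate hub at {facilities[i].name}",
                kind="candidate_hub",
                sub_county=facilities[i].sub_county,
                lat=facilities[i].lat,
                lon=facilities[i].lon,
                machine_service_rate=config.poc_machine_rate,
                n_machines=config.candidate_hub_machines,
                vl_fraction=1.0,
                fixed_open=False,
                level=facilities[i].level,
            )
        )

    distance = pd.DataFrame(
        {
            s.id: [
                config.circuity_factor
                * haversine_km(f.lat, f.lon, s.lat, s.lon)
                for f in facilities
            ]
            for s in sites
        },
        index=[f.id for f in facilities],
    )

    instance = ProblemInstance(
        facilities=facilities,
        sites=sites,
        distance_km=distance,
        transport=TransportParams("motorbike"),
        batching=BatchingPolicy("twice_weekly"),
        n_added_hubs=0,
        fairness=False,
    )
    _check_generated(instance, config)
    return instance


def _remote_weights(n_labs: int) -> np.ndarray:
    w = np.ones(n_labs - 1)
    w[0] = 2.0  # the nearer distant lab historically takes more misrouting
    return w / w.sum()


def _pick_candidates(
    config, levels, derived, sc_idx, hosts, lat, lon, existing_coords
) -> List[int]:
    """Site candidate hubs where current testing access is worst.

    New machines are proposed for under-served areas: within each
    sub-county the eligible (level-3+) clinic farthest from every existing
    testing site is chosen first, then remaining slots go to the globally
    least-covered eligible clinics.  This mirrors the coverage logic behind
    the fairness constraint.
    """
    hosts_set = set(hosts)

    def coverage_gap(i: int) -> float:
        return min(
            haversine_km(lat[i], lon[i], clat, clon)
            for clat, clon in existing_coords
        )

    chosen: List[int] = []
    for k in range(config.n_subcounties):
        members = [
            i
            for i in range(len(levels))
            if sc_idx[i] == k and i not in hosts_set
        ]
        if not members:
            continue
        lvl3 = [i for i in members if levels[i] >= 3]
        if not lvl3:
            # promote the busiest clinic so the fairness quota stays feasible
            best = max(members, key=lambda i: derived[i])
            levels[best] = 3
            lvl3 = [best]
        chosen.append(max(lvl3, key=lambda i: (coverage_gap(i), -i)))
    pool = sorted(
        (
            i
            for i in range(len(levels))
            if levels[i] >= 3 and i not in hosts_set and i not in chosen
        ),
        key=lambda i: (-coverage_gap(i), i),
    )
    chosen.extend(pool[: max(0, config.n_candidate_hubs - len(chosen))])
    if len(chosen) < config.n_candidate_hubs:
        raise GenerationError("not enough level-3+ clinics for candidate hubs")
    return chosen[: config.n_candidate_hubs]


def _check_generated(instance: ProblemInstance, config: GeneratorConfig) -> None:
    from .allocation import baseline_background, site_capacity
    from .core import ValidationError

    total = instance.total_daily_demand()
    background = baseline_background(instance)
    capacity = 0.0
    try:
        for s in instance.sites:
            capacity += site_capacity(
                s,
                background_demand=background.get(s.id, 0.0),
                utilization_cap=instance.utilization_cap,
            )
    except ValidationError as err:
        raise GenerationError(
            f"config yields an unusable site: {err}"
        ) from err
    if total > capacity:
        raise GenerationError(
            f"generated demand {total:.1f}/day exceeds total system capacity "
            f"{capacity:.1f}/day; lower the utilization targets or demand"
        )
    assigned = {lab.id: 0.0 for lab in instance.central_labs}
    for f in instance.facilities:
        assigned[f.current_site_id] += f.daily_demand
    for lab in instance.central_labs:
        rho = (
            (assigned[lab.id] + background[lab.id])
            / (lab.n_entry_servers * lab.entry_service_rate)
        )
        if rho >= 1:
            raise GenerationError(
                f"lab {lab.id} unstable under the existing network (rho={rho:.4f})"
            )


# ---------------------------------------------------------------------------
# small fixture for the enumeration oracle
# ---------------------------------------------------------------------------

def make_fixture_small(seed: int = 0) -> ProblemInstance:
    """A 7-clinic, 2-lab, 1-hub, 3-candidate instance, enumeration-sized.

    Demands and coordinates are randomized under ``seed``; capacities are
    tight enough that the capacity constraints bind on some draws.  Feasible
    for 0-3 added hubs by construction (checked at generation).
    """
    rng = np.random.default_rng(seed)
    nf = 7
    lat = rng.uniform(-0.30, 0.0, nf)
    lon = rng.uniform(34.5, 34.9, nf)
    levels = rng.choice([2, 3, 4, 5], size=nf, p=[0.3, 0.3, 0.25, 0.15])
    sub = ["A" if x < 34.7 else "B" for x in lon]
    daily = np.minimum(rng.lognormal(0.4, 0.8, nf), 8.0)
    daily[rng.integers(0, nf)] = 0.0  # keep one zero-demand clinic

    lab_coords = [(-0.09, 34.75), (-0.10, 35.35)]  # one in-county, one distant
    lab_ids = ["L1", "L2"]
    current = np.zeros(nf, dtype=int)
    current[rng.random(nf) < 0.25] = 1

    facilities = []
    for i in range(nf):
        child, adult = _volumes_from_daily(float(daily[i]))
        facilities.append(
            Facility(
                id=f"F{i + 1}",
                name=f"Clinic {i + 1}",
                level=int(levels[i]),
                sub_county=sub[i],
                lat=float(lat[i]),
                lon=float(lon[i]),
                annual_child_volume=child,
                annual_adult_volume=adult,
                current_site_id=lab_ids[current[i]],
            )
        )
    sites = [
        TestingSite(
            id=lab_ids[j],
            name=f"Lab {j + 1}",
            kind="central_lab",
            sub_county="A" if j == 0 else "out_of_county",
            lat=lab_coords[j][0],
            lon=lab_coords[j][1],
            machine_service_rate=40.0,
            n_machines=1,
            n_entry_servers=1,
            entry_service_rate=30.0,
            kisumu_fraction=0.6 if j == 0 else 0.3,
            fixed_open=True,
        )
        for j in range(2)
    ]
    sites.append(
        TestingSite(
            id="H1",
            name="Existing hub",
            kind="existing_hub",
            sub_county="A",
            lat=float(rng.uniform(-0.25, -0.05)),
            lon=float(rng.uniform(34.55, 34.68)),
            machine_service_rate=12.0,
            n_machines=1,
            vl_fraction=1.0,
            fixed_open=True,
            level=4,
        )
    )
    cand_levels = [3, 4, 5]
    for k in range(3):
        sites.append(
            TestingSite(
                id=f"C{k + 1}",
                name=f"Candidate {k + 1}",
                kind="candidate_hub",
                sub_county="A" if k == 0 else "B",
                lat=float(rng.uniform(-0.3, 0.0)),
                lon=float(rng.uniform(34.5, 34.9)),
                machine_service_rate=12.0,
                n_machines=1,
                vl_fraction=1.0,
                fixed_open=False,
                level=cand_levels[k],
            )
        )
    distance = pd.DataFrame(
        {
            s.id: [
                1.3 * haversine_km(f.lat, f.lon, s.lat, s.lon)
                for f in facilities
            ]
            for s in sites
        },
        index=[f.id for f in facilities],
    )
    instance = ProblemInstance(
        facilities=facilities,
        sites=sites,
        distance_km=distance,
        transport=TransportParams("motorbike"),
        batching=BatchingPolicy("twice_weekly"),
    )
    # stability / feasibility guard: thin out demand if the draw was too hot
    from .allocation import baseline_background, site_capacity

    for _ in range(20):
        background = baseline_background(instance)
        fixed_cap = sum(
            site_capacity(s, background.get(s.id, 0.0), 0.9)
            for s in instance.sites
            if s.fixed_open
        )
        lab_ok = all(
            (sum(
                f.daily_demand
                for f in instance.facilities
                if f.current_site_id == lab.id
            ) + background[lab.id])
            < 0.95 * lab.n_entry_servers * lab.entry_service_rate
            for lab in instance.central_labs
        )
        if lab_ok and instance.total_daily_demand() <= fixed_cap:
            break
        for f in instance.facilities:
            f.annual_adult_volume = int(f.annual_adult_volume * 0.8)
            f.annual_child_volume = int(f.annual_child_volume * 0.8)
            f.__post_init__()
    else:
        raise GenerationError("could not thin the small fixture into feasibility")
    return instance
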