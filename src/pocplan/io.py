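"""CSV / JSON / GeoJSON readers and writers.

Three CSV schemas describe a planning instance (clinics, testing sites and
a long-format distance table); scenario results are written as a JSON
report plus a per-clinic CSV, and the referral network as a GeoJSON
FeatureCollection for mapping.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    BatchingPolicy,
    Facility,
    ProblemInstance,
    TestingSite,
    TransportParams,
    ValidationError,
)
from .allocation import ReferralNetwork
from .evaluation import FacilityTAT, SensitivityResult, SystemReport
from .queueing import QueueMetrics

__all__ = [
    "FACILITY_COLUMNS",
    "SITE_COLUMNS",
    "DISTANCE_COLUMNS",
    "write_instance",
    "read_instance",
    "instances_equal",
    "write_report_json",
    "read_report_json",
    "write_report_csv",
    "write_sensitivity_csv",
    "write_network_geojson",
]

FACILITY_COLUMNS = [
    "id",
    "name",
    "level",
    "sub_county",
    "lat",
    "lon",
    "annual_child_volume",
    "annual_adult_volume",
    "current_site_id",
]
SITE_COLUMNS = [
    "id",
    "name",
    "kind",
    "sub_county",
    "lat",
    "lon",
    "n_entry_servers",
    "entry_service_rate",
    "machine_service_rate",
    "n_machines",
    "kisumu_fraction",
    "vl_fraction",
    "fixed_open",
    "level",
]
DISTANCE_COLUMNS = ["origin_id", "dest_id", "km"]


def _fmt_float(v) -> str:
    """Shortest decimal that round-trips the value exactly."""
    return repr(float(v))


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{what}: missing required column(s) {', '.join(missing)}"
        )


# ---------------------------------------------------------------------------
# instance CSVs
# ---------------------------------------------------------------------------

def write_instance(instance: ProblemInstance, outdir: Union[str, Path]) -> None:
    """Write facilities.csv, sites.csv, distances.csv and config.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fac = pd.DataFrame(
        [
            {
                "id": f.id,
                "name": f.name,
                "level": f.level,
                "sub_county": f.sub_county,
                "lat": f.lat,
                "lon": f.lon,
                "annual_child_volume": f.annual_child_volume,
                "annual_adult_volume": f.annual_adult_volume,
                "current_site_id": f.current_site_id,
            }
            for f in instance.facilities
        ]
    )
    fac.to_csv(outdir / "facilities.csv", index=False, float_format=_fmt_float)
    sites = pd.DataFrame(
        [
            {
                "id": s.id,
                "name": s.name,
                "kind": s.kind,
                "sub_county": s.sub_county,
                "lat": s.lat,
                "lon": s.lon,
                "n_entry_servers": s.n_entry_servers,
                "entry_service_rate": s.entry_service_rate,
                "machine_service_rate": s.machine_service_rate,
                "n_machines": s.n_machines,
                "kisumu_fraction": s.kisumu_fraction,
                "vl_fraction": s.vl_fraction,
                "fixed_open": s.fixed_open,
                "level": "" if s.level is None else s.level,
            }
            for s in instance.sites
        ]
    )
    sites.to_csv(outdir / "sites.csv", index=False, float_format=_fmt_float)
    long = instance.distance_km.stack().rename("km").reset_index()
    long.columns = DISTANCE_COLUMNS
    if instance.travel_time_min is not None:
        minutes = instance.travel_time_min.stack().rename("minutes").reset_index()
        minutes.columns = ["origin_id", "dest_id", "minutes"]
        long = long.merge(minutes, on=["origin_id", "dest_id"], how="left")
    long.to_csv(outdir / "distances.csv", index=False, float_format=_fmt_float)
    settings = {
        "transport": dataclasses.asdict(instance.transport),
        "batching": dataclasses.asdict(instance.batching),
        "n_added_hubs": instance.n_added_hubs,
        "fairness": instance.fairness,
        "utilization_cap": instance.utilization_cap,
        "workday_hours": instance.workday_hours,
        "workdays_per_month": instance.workdays_per_month,
    }
    (outdir / "config.json").write_text(json.dumps(settings, indent=2))


def read_instance(indir: Union[str, Path]) -> ProblemInstance:
    """Read an instance written by :func:`write_instance`."""
    indir = Path(indir)
    fac_df = pd.read_csv(indir / "facilities.csv", float_precision="round_trip")
    _require_columns(fac_df, FACILITY_COLUMNS, "facilities.csv")
    site_df = pd.read_csv(indir / "sites.csv", float_precision="round_trip")
    _require_columns(site_df, SITE_COLUMNS[:-1], "sites.csv")
    dist_df = pd.read_csv(indir / "distances.csv", float_precision="round_trip")
    _require_columns(dist_df, DISTANCE_COLUMNS, "distances.csv")

    settings_path = indir / "config.json"
    transport = TransportParams()
    batching = BatchingPolicy()
    extra = {}
    if settings_path.exists():
        raw = json.loads(settings_path.read_text())
        transport = TransportParams(**raw.get("transport", {}))
        batching = BatchingPolicy(**raw.get("batching", {}))
        extra = {
            k: raw[k]
            for k in (
                "n_added_hubs",
                "fairness",
                "utilization_cap",
                "workday_hours",
                "workdays_per_month",
            )
            if k in raw
        }

    facilities = [
        Facility(
            id=str(r.id),
            name=str(r.name),
            level=int(r.level),
            sub_county=str(r.sub_county),
            lat=float(r.lat),
            lon=float(r.lon),
            annual_child_volume=_num(r.annual_child_volume),
            annual_adult_volume=_num(r.annual_adult_volume),
            current_site_id=str(r.current_site_id),
        )
        for r in fac_df.itertuples()
    ]
    sites = []
    for r in site_df.itertuples():
        level = getattr(r, "level", None)
        if level is not None and not (
            isinstance(level, float) and math.isnan(level)
        ):
            level = int(level)
        else:
            level = None
        sites.append(
            TestingSite(
                id=str(r.id),
                name=str(r.name),
                kind=str(r.kind),
                sub_county=str(r.sub_county),
                lat=float(r.lat),
                lon=float(r.lon),
                n_entry_servers=int(r.n_entry_servers),
                entry_service_rate=float(r.entry_service_rate),
                machine_service_rate=float(r.machine_service_rate),
                n_machines=int(r.n_machines),
                kisumu_fraction=float(r.kisumu_fraction),
                vl_fraction=float(r.vl_fraction),
                fixed_open=_to_bool(r.fixed_open),
                level=level,
            )
        )
    distance = dist_df.pivot(index="origin_id", columns="dest_id", values="km")
    distance = distance.loc[[f.id for f in facilities], [s.id for s in sites]]
    distance.index.name = None
    distance.columns.name = None
    travel_time = None
    if "minutes" in dist_df.columns and dist_df["minutes"].notna().any():
        travel_time = dist_df.pivot(
            index="origin_id", columns="dest_id", values="minutes"
        ).loc[[f.id for f in facilities], [s.id for s in sites]]
        travel_time.index.name = None
        travel_time.columns.name = None
    return ProblemInstance(
        facilities=facilities,
        sites=sites,
        distance_km=distance,
        transport=transport,
        batching=batching,
        travel_time_min=travel_time,
        **extra,
    )


def _num(x) -> float:
    """Keep integers as ints so CSV round-trips are exact."""
    f = float(x)
    return int(f) if f.is_integer() else f


def _to_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    return str(x).strip().lower() in ("true", "1", "yes")


def instances_equal(a: ProblemInstance, b: ProblemInstance) -> bool:
    """Field-by-field equality (DataFrames compared by value)."""
    if a.facilities != b.facilities or a.sites != b.sites:
        return False
    if not a.distance_km.round(12).equals(b.distance_km.round(12)):
        return False
    return (
        a.transport == b.transport
        and a.batching == b.batching
        and a.n_added_hubs == b.n_added_hubs
        and a.fairness == b.fairness
        and a.utilization_cap == b.utilization_cap
        and a.workday_hours == b.workday_hours
        and a.workdays_per_month == b.workdays_per_month
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report_json(report: SystemReport, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def read_report_json(path: Union[str, Path]) -> SystemReport:
    """Rebuild a SystemReport from its JSON form (lossless round trip)."""
    d = json.loads(Path(path).read_text())
    tats = [
        FacilityTAT(
            facility_id=t["facility_id"],
            site_id=t["site_id"],
            batching_min=t["batching_min"],
            transport_min=t["transport_min"],
            waiting_min=t["waiting_min"],
        )
        for t in d["facility_tats"]
    ]
    metrics = {
        sid: [
            QueueMetrics(
                utilization=m["utilization"],
                p_wait=m["p_wait"],
                wq=m["wq_days"],
                w=m["w_days"],
                stable=m["stable"],
            )
            for m in stages
        ]
        for sid, stages in d["site_metrics"].items()
    }
    network = ReferralNetwork(
        open_sites=set(d["open_sites"]),
        assignment=dict(d["assignment"]),
        objective_value=d["objective_value"],
        solver_status=d["solver_status"],
    )
    return SystemReport(
        scenario=d["scenario"],
        facility_tats=tats,
        mean_tat_min=d["mean_tat_min"],
        sd_tat_min=d["sd_tat_min"],
        total_sample_hours=d["total_sample_hours"],
        component_shares=dict(d["component_shares"]),
        site_metrics=metrics,
        site_loads=dict(d["site_loads"]),
        network=network,
        warnings=list(d["warnings"]),
    )


def write_report_csv(report: SystemReport, path: Union[str, Path]) -> None:
    rows = [
        {
            "facility_id": t.facility_id,
            "site_id": t.site_id,
            "batching_min": t.batching_min,
            "transport_min": t.transport_min,
            "waiting_min": t.waiting_min,
            "total_min": t.total_min,
            "total_hours": t.total_min / 60.0,
        }
        for t in report.facility_tats
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_sensitivity_csv(
    results: Sequence[SensitivityResult], path: Union[str, Path]
) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# GeoJSON export
# ---------------------------------------------------------------------------

def write_network_geojson(
    instance: ProblemInstance,
    network: ReferralNetwork,
    path: Union[str, Path],
) -> None:
    """Points for clinics and open sites, lines for referral links.

    Site roles follow the usual map legend: central labs, existing hubs and
    added (newly opened candidate) hubs; clinics carry an ``assigned_to``
    property.
    """
    features: List[dict] = []
    for s in instance.sites:
        if s.id not in network.open_sites:
            continue
        role = "added_hub" if s.kind == "candidate_hub" else s.kind
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [s.lon, s.lat]},
                "properties": {"id": s.id, "name": s.name, "role": role},
            }
        )
    site_by_id = instance.site_by_id
    for f in instance.facilities:
        sid = network.assignment[f.id]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [f.lon, f.lat]},
                "properties": {
                    "id": f.id,
                    "name": f.name,
                    "role": "facility",
                    "assigned_to": sid,
                },
            }
        )
        s = site_by_id[sid]
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[f.lon, f.lat], [s.lon, s.lat]],
                },
                "properties": {
                    "role": "referral_link",
                    "facility": f.id,
                    "site": sid,
                },
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(collection))
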