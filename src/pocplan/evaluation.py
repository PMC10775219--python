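"""Post-hoc TAT evaluation, scenario runner and one-way sensitivity sweep.

Once a referral network is fixed, every clinic's expected turnaround time
(TAT) decomposes additively into batching delay + transport time + waiting
time at its testing site.  Waiting is a steady-state expectation, so all
clinics assigned to the same site share the same waiting component.  The
system summary reports the unweighted mean/SD of TAT across clinics, the
demand-weighted cumulative sample-hours per working day, and the
demand-weighted share of each TAT component.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    BatchingPolicy,
    ProblemInstance,
    TransportParams,
    ValidationError,
)
from .allocation import (
    AllocationConfig,
    ReferralNetwork,
    baseline_background,
    existing_network,
    solve_allocation,
)
from .queueing import (
    QueueMetrics,
    SiteLoad,
    UnstableQueueError,
    central_lab_wait,
    poc_hub_wait,
    site_queue_metrics,
)

__all__ = [
    "FacilityTAT",
    "SystemReport",
    "SensitivityResult",
    "evaluate_network",
    "run_scenario",
    "sensitivity_sweep",
    "default_sensitivity_grid",
]

logger = logging.getLogger(__name__)

MINUTES_PER_HOUR = 60.0


@dataclass(frozen=True)
class FacilityTAT:
    """One clinic's expected TAT decomposition, in minutes."""

    facility_id: str
    site_id: str
    batching_min: float
    transport_min: float
    waiting_min: float

    @property
    def total_min(self) -> float:
        return self.batching_min + self.transport_min + self.waiting_min


@dataclass
class SystemReport:
    """System-level summary of one scenario run."""

    scenario: str
    facility_tats: List[FacilityTAT]
    mean_tat_min: float
    sd_tat_min: float
    total_sample_hours: float  # sum_i d_i * TAT_i / 60, per working day
    component_shares: Dict[str, float]  # batching / transport / waiting
    site_metrics: Dict[str, List[QueueMetrics]]
    site_loads: Dict[str, float]
    network: ReferralNetwork
    warnings: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "mean_tat_min": self.mean_tat_min,
            "sd_tat_min": self.sd_tat_min,
            "total_sample_hours": self.total_sample_hours,
            "component_shares": dict(self.component_shares),
            "facility_tats": [
                {
                    "facility_id": t.facility_id,
                    "site_id": t.site_id,
                    "batching_min": t.batching_min,
                    "transport_min": t.transport_min,
                    "waiting_min": t.waiting_min,
                    "total_min": t.total_min,
                }
                for t in self.facility_tats
            ],
            "site_metrics": {
                sid: [
                    {
                        "utilization": m.utilization,
                        "p_wait": m.p_wait,
                        "wq_days": m.wq,
                        "w_days": m.w,
                        "stable": m.stable,
                    }
                    for m in stages
                ]
                for sid, stages in self.site_metrics.items()
            },
            "site_loads": dict(self.site_loads),
            "open_sites": sorted(self.network.open_sites),
            "assignment": dict(self.network.assignment),
            "objective_value": self.network.objective_value,
            "solver_status": self.network.solver_status,
            "warnings": list(self.warnings),
        }


@dataclass(frozen=True)
class SensitivityResult:
    """One cell of the sensitivity table."""

    parameter: str
    setting: str
    scenario: str
    mean_tat_min: float
    sd_tat_min: float
    percent_change_vs_baseline: float
    status: str = "ok"


# ---------------------------------------------------------------------------
# network evaluation
# ---------------------------------------------------------------------------

def evaluate_network(
    instance: ProblemInstance,
    network: ReferralNetwork,
    pooled_entry_rate: bool = False,
) -> SystemReport:
    """Compute the full TAT decomposition of a referral network."""
    site_by_id = instance.site_by_id
    for fid, sid in network.assignment.items():
        if sid not in network.open_sites:
            raise ValidationError(
                f"facility {fid} is assigned to closed site {sid}"
            )
    background = baseline_background(instance)
    loads: Dict[str, float] = {sid: 0.0 for sid in network.open_sites}
    for f in instance.facilities:
        loads[network.assignment[f.id]] += f.daily_demand

    day_min = instance.workday_hours * MINUTES_PER_HOUR
    waiting_min: Dict[str, float] = {}
    metrics: Dict[str, List[QueueMetrics]] = {}
    warnings: List[str] = []
    for sid in sorted(network.open_sites):
        site = site_by_id[sid]
        load = SiteLoad(
            site_id=sid,
            assigned_demand=loads[sid],
            background_demand=background.get(sid, 0.0)
            if site.is_central_lab
            else 0.0,
        )
        try:
            if site.is_central_lab:
                w_days = central_lab_wait(site, load, pooled_entry_rate)
            else:
                w_days = poc_hub_wait(site, load)
        except UnstableQueueError as err:
            raise UnstableQueueError(
                f"site {sid} is unstable under this network: {err}",
                utilization=err.utilization,
                stage=err.stage,
            ) from err
        stages = site_queue_metrics(site, load, pooled_entry_rate)
        rho = max(m.utilization for m in stages)
        if rho > instance.utilization_cap:
            msg = (
                f"site {sid}: utilization {rho:.3f} exceeds the "
                f"{instance.utilization_cap:.0%} planning cap"
            )
            warnings.append(msg)
            logger.warning(msg)
        waiting_min[sid] = w_days * day_min
        metrics[sid] = stages

    batching = instance.batching.expected_delay_min
    tats = [
        FacilityTAT(
            facility_id=f.id,
            site_id=network.assignment[f.id],
            batching_min=batching,
            transport_min=instance.transport_minutes(
                f.id, network.assignment[f.id]
            ),
            waiting_min=waiting_min[network.assignment[f.id]],
        )
        for f in instance.facilities
    ]
    totals = np.array([t.total_min for t in tats])
    demand = np.array([f.daily_demand for f in instance.facilities])
    weighted = {
        "batching": float(np.dot(demand, [t.batching_min for t in tats])),
        "transport": float(np.dot(demand, [t.transport_min for t in tats])),
        "waiting": float(np.dot(demand, [t.waiting_min for t in tats])),
    }
    denom = sum(weighted.values())
    if denom > 0:
        shares = {k: v / denom for k, v in weighted.items()}
    else:  # degenerate zero-demand system: fall back to unweighted sums
        sums = {
            "batching": sum(t.batching_min for t in tats),
            "transport": sum(t.transport_min for t in tats),
            "waiting": sum(t.waiting_min for t in tats),
        }
        total = sum(sums.values())
        shares = {k: (v / total if total else 0.0) for k, v in sums.items()}
    return SystemReport(
        scenario="",
        facility_tats=tats,
        mean_tat_min=float(totals.mean()) if len(totals) else 0.0,
        sd_tat_min=float(totals.std(ddof=1)) if len(totals) > 1 else 0.0,
        total_sample_hours=float(np.dot(demand, totals)) / MINUTES_PER_HOUR,
        component_shares=shares,
        site_metrics=metrics,
        site_loads=loads,
        network=network,
        warnings=warnings + list(network.warnings),
    )


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def run_scenario(
    instance: ProblemInstance,
    scenario: int,
    p_add: Optional[int] = None,
    fairness: Optional[bool] = None,
    pooled_entry_rate: bool = False,
) -> SystemReport:
    """Run one of the three network scenarios and evaluate it.

    1. the existing referral network, central labs only (no optimization);
    2. central labs + existing hubs, optimized referral network (no new hubs);
    3. as 2 plus ``p_add`` optimally placed new hubs (0-7).
    """
    if scenario not in (1, 2, 3):
        raise ValidationError("scenario must be 1, 2 or 3")
    if fairness is None:
        fairness = instance.fairness
    if scenario == 1:
        network = existing_network(instance)
    else:
        if scenario == 2:
            p_add = 0
        else:
            p_add = instance.n_added_hubs if p_add is None else p_add
            if not (0 <= p_add <= 7):
                raise ValidationError("scenario 3 expects 0-7 added hubs")
        config = AllocationConfig.from_instance(
            instance,
            n_added_hubs=p_add,
            fairness=fairness if scenario == 3 else False,
            pooled_entry_rate=pooled_entry_rate,
        )
        network = solve_allocation(instance, config)
    report = evaluate_network(instance, network, pooled_entry_rate)
    label = f"scenario_{scenario}"
    if scenario == 3:
        label += f"_p{p_add}"
    report.scenario = label
    return report


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------

Transform = Callable[[ProblemInstance], ProblemInstance]


def _scale_lab_rates(factor: float) -> Transform:
    def apply(instance: ProblemInstance) -> ProblemInstance:
        inst = copy.deepcopy(instance)
        for s in inst.sites:
            if s.is_central_lab:
                s.entry_service_rate *= factor
                s.machine_service_rate *= factor
        return inst

    return apply


def _add_hub_machines(extra: int, kinds: Tuple[str, ...]) -> Transform:
    def apply(instance: ProblemInstance) -> ProblemInstance:
        inst = copy.deepcopy(instance)
        for s in inst.sites:
            if s.kind in kinds:
                s.n_machines += extra
        return inst

    return apply


def _set_transport(**kwargs) -> Transform:
    def apply(instance: ProblemInstance) -> ProblemInstance:
        inst = copy.deepcopy(instance)
        merged = {
            "mode": inst.transport.mode,
            "road_coeff": inst.transport.road_coeff,
            "weather_coeff": inst.transport.weather_coeff,
        }
        merged.update(kwargs)
        inst.transport = TransportParams(**merged)
        return inst

    return apply


def _set_batching(mode: str) -> Transform:
    def apply(instance: ProblemInstance) -> ProblemInstance:
        inst = copy.deepcopy(instance)
        inst.batching = BatchingPolicy(mode, inst.batching.workday_hours)
        return inst

    return apply


def default_sensitivity_grid() -> List[Tuple[str, str, Transform]]:
    """The one-way sweep: (parameter, setting label, instance transform).

    Baseline (not listed) is twice-weekly batching, motorbike transport,
    average road and weather conditions.
    """
    return [
        ("central_lab_capacity", "x1.25", _scale_lab_rates(1.25)),
        ("central_lab_capacity", "x1.5", _scale_lab_rates(1.5)),
        ("existing_hub_machines", "+1", _add_hub_machines(1, ("existing_hub",))),
        ("existing_hub_machines", "+2", _add_hub_machines(2, ("existing_hub",))),
        ("added_hub_machines", "+1", _add_hub_machines(1, ("candidate_hub",))),
        ("added_hub_machines", "+2", _add_hub_machines(2, ("candidate_hub",))),
        ("transport_mode", "walk", _set_transport(mode="walk")),
        ("transport_mode", "bike", _set_transport(mode="bike")),
        ("transport_mode", "car", _set_transport(mode="car")),
        ("road_condition", "good", _set_transport(road_coeff=0.8)),
        ("road_condition", "bad", _set_transport(road_coeff=1.2)),
        ("weather_condition", "good", _set_transport(weather_coeff=0.8)),
        ("weather_condition", "bad", _set_transport(weather_coeff=1.2)),
        ("batching_mode", "daily", _set_batching("daily")),
        ("batching_mode", "once_weekly", _set_batching("once_weekly")),
    ]


def sensitivity_sweep(
    instance: ProblemInstance,
    grid: Optional[Sequence[Tuple[str, str, Transform]]] = None,
    scenarios: Sequence[int] = (1, 2, 3),
    p_add: int = 7,
    fairness: bool = True,
) -> List[SensitivityResult]:
    """One run per (parameter setting x scenario), re-solving each network.

    Percent changes are against a cached baseline run of the same scenario
    (scenario 3 uses ``p_add`` added hubs under the fairness constraint,
    matching how the headline results are reported).  Per-run failures are
    recorded and the sweep continues.
    """
    if grid is None:
        grid = default_sensitivity_grid()
    baselines: Dict[int, SystemReport] = {
        sc: run_scenario(instance, sc, p_add=p_add, fairness=fairness)
        for sc in scenarios
    }
    results: List[SensitivityResult] = []
    for sc in scenarios:
        base = baselines[sc]
        results.append(
            SensitivityResult(
                parameter="baseline",
                setting="baseline",
                scenario=base.scenario,
                mean_tat_min=base.mean_tat_min,
                sd_tat_min=base.sd_tat_min,
                percent_change_vs_baseline=0.0,
            )
        )
    for parameter, setting, transform in grid:
        for sc in scenarios:
            base = baselines[sc]
            try:
                modified = transform(instance)
                report = run_scenario(modified, sc, p_add=p_add, fairness=fairness)
                change = (
                    100.0
                    * (report.mean_tat_min - base.mean_tat_min)
                    / base.mean_tat_min
                )
                results.append(
                    SensitivityResult(
                        parameter=parameter,
                        setting=setting,
                        scenario=base.scenario,
                        mean_tat_min=report.mean_tat_min,
                        sd_tat_min=report.sd_tat_min,
                        percent_change_vs_baseline=change,
                    )
                )
            except Exception as err:  # record and continue the sweep
                logger.warning(
                    "sensitivity run failed (%s=%s, %s): %s",
                    parameter,
                    setting,
                    base.scenario,
                    err,
                )
                results.append(
                    SensitivityResult(
                        parameter=parameter,
                        setting=setting,
                        scenario=base.scenario,
                        mean_tat_min=float("nan"),
                        sd_tat_min=float("nan"),
                        percent_change_vs_baseline=float("nan"),
                        status=f"failed: {err}",
                    )
                )
    return results
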