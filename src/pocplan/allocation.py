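"""Hub selection and referral-network optimization.

The planning problem is a capacitated facility-location binary program.
For clinics ``i`` and testing sites ``j`` let ``x_ij`` indicate that clinic
``i`` refers its samples to site ``j`` and ``y_j`` that candidate hub ``j``
is opened.  With per-clinic daily demand ``d_i``, batching delay ``B`` and
transport time ``t_ij`` (minutes), the model is

    min  sum_i  w_i (B + t_ij) x_ij          (w_i = d_i, demand weighting)
    s.t. sum_j x_ij = 1                       for every clinic i
         x_ij <= y_j                          for candidate sites j
         sum_i d_i x_ij <= cap_j y_j          capacity at 90% utilization
         sum_{j in candidates} y_j = p_add    pre-specified number of new hubs
         y_j = 1                              for central labs, existing hubs
         sum_{j in sub-county k} y_j >= 1     optional fairness constraint

Queue waiting time is deliberately *not* part of the objective (it would
make the program nonlinear); it is added afterwards by the evaluation
layer.  ``cap_j`` is the natural big-M, so the program stays a pure binary
linear model.  The solver backend is HiGHS via :func:`scipy.optimize.milp`;
``bruteforce_allocation`` is an exhaustive-enumeration oracle for small
instances.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .core import ProblemInstance, TestingSite, ValidationError
from .queueing import background_rate

__all__ = [
    "AllocationConfig",
    "ReferralNetwork",
    "InfeasibleAllocationError",
    "eligible_candidates",
    "site_capacity",
    "baseline_background",
    "solve_allocation",
    "bruteforce_allocation",
    "existing_network",
]

logger = logging.getLogger(__name__)


class InfeasibleAllocationError(RuntimeError):
    """The program has no feasible referral network; names the likely cause."""


@dataclass(frozen=True)
class AllocationConfig:
    """Dials of the optimization model."""

    n_added_hubs: int = 0
    fairness: bool = False
    utilization_cap: float = 0.9
    eligible_levels: FrozenSet[int] = frozenset({3, 4, 5})
    demand_weighted: bool = True
    labs_only: bool = False  # close all hubs (optimized labs-only variant)
    pooled_entry_rate: bool = False
    time_limit_s: float = 60.0
    # production solver settings: a 0.1% relative gap and pruning each
    # clinic's hub choices to its nearest hubs (labs always stay allowed)
    # keep county-scale instances tractable; set mip_gap=0 and
    # nearest_hub_limit=None for exact solves on small instances
    mip_gap: float = 1e-3
    nearest_hub_limit: Optional[int] = 8

    def __post_init__(self) -> None:
        if self.n_added_hubs < 0:
            raise ValidationError("n_added_hubs must be non-negative")
        if not (0 < self.utilization_cap <= 1):
            raise ValidationError("utilization_cap must be in (0, 1]")

    @staticmethod
    def from_instance(instance: ProblemInstance, **overrides) -> "AllocationConfig":
        base = dict(
            n_added_hubs=instance.n_added_hubs,
            fairness=instance.fairness,
            utilization_cap=instance.utilization_cap,
        )
        base.update(overrides)
        return AllocationConfig(**base)


@dataclass
class ReferralNetwork:
    """A solved (or given) opening + assignment decision."""

    open_sites: Set[str]
    assignment: Dict[str, str]  # facility id -> site id
    objective_value: float  # demand-weighted batching+transport minutes
    solver_status: str  # optimal | infeasible | relaxed_fairness | existing
    relaxed_sub_counties: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def eligible_candidates(
    sites: Sequence[TestingSite], config: AllocationConfig
) -> List[str]:
    """Candidate hubs whose host facility level allows a POC machine.

    Levels 3-5 (health centres, county hospitals, county referral
    hospitals) have the infrastructure to host machines; fixed-open sites
    pass unconditionally.
    """
    out = []
    for s in sites:
        if s.fixed_open:
            out.append(s.id)
        elif s.kind == "candidate_hub":
            if s.level is None:
                raise ValidationError(
                    f"candidate hub {s.id} has no facility level"
                )
            if s.level in config.eligible_levels:
                out.append(s.id)
    return out


def site_capacity(
    site: TestingSite,
    background_demand: float = 0.0,
    utilization_cap: float = 0.9,
    pooled_entry_rate: bool = False,
) -> float:
    """Daily in-county samples a site may accept at the utilization cap.

    Hubs: ``n_machines * rate * vl_fraction * cap``.  Central labs: the cap
    applies to the bottleneck of the two stages, and the constant
    out-of-county background is subtracted from what remains.
    """
    if site.is_hub:
        return (
            site.n_machines
            * site.machine_service_rate
            * site.vl_fraction
            * utilization_cap
        )
    entry_capacity = site.n_entry_servers * site.entry_service_rate
    if pooled_entry_rate:
        entry_capacity = site.entry_service_rate
    net = utilization_cap * min(entry_capacity, site.machine_service_rate)
    net -= background_demand
    if net <= 0:
        raise ValidationError(
            f"central lab {site.id}: out-of-county background "
            f"({background_demand:.1f}/day) exhausts its capped capacity"
        )
    return net


def baseline_background(instance: ProblemInstance) -> Dict[str, float]:
    """Out-of-county arrival rate per central lab.

    Derived from each lab's in-county intake under the *existing* referral
    network and its in-county share; held constant across scenarios.
    """
    assigned: Dict[str, float] = {lab.id: 0.0 for lab in instance.central_labs}
    for f in instance.facilities:
        assigned[f.current_site_id] += f.daily_demand
    return {
        lab.id: background_rate(lab, assigned[lab.id])
        for lab in instance.central_labs
    }


def _capacities(
    instance: ProblemInstance, config: AllocationConfig
) -> Dict[str, float]:
    background = baseline_background(instance)
    caps = {}
    for s in instance.sites:
        caps[s.id] = site_capacity(
            s,
            background_demand=background.get(s.id, 0.0),
            utilization_cap=config.utilization_cap,
            pooled_entry_rate=config.pooled_entry_rate,
        )
    return caps


def _objective_value(
    instance: ProblemInstance,
    assignment: Dict[str, str],
    config: AllocationConfig,
) -> float:
    b = instance.batching.expected_delay_min
    total = 0.0
    for f in instance.facilities:
        w = f.daily_demand if config.demand_weighted else 1.0
        total += w * (b + instance.transport_minutes(f.id, assignment[f.id]))
    return total


def _considered_sites(
    instance: ProblemInstance, config: AllocationConfig
) -> tuple[List[TestingSite], List[TestingSite]]:
    """(fixed-open sites, eligible candidate sites) under the config."""
    if config.labs_only:
        fixed = list(instance.central_labs)
        return fixed, []
    eligible = set(eligible_candidates(instance.sites, config))
    fixed = [s for s in instance.sites if s.fixed_open]
    cands = [
        s for s in instance.sites if not s.fixed_open and s.id in eligible
    ]
    return fixed, cands


def _fairness_groups(
    instance: ProblemInstance,
    fixed: Sequence[TestingSite],
    cands: Sequence[TestingSite],
) -> tuple[Dict[str, List[str]], List[str]]:
    """Sub-counties needing a hub -> candidate ids there; plus relaxed ones.

    A sub-county is covered outright if it already contains an existing hub
    (existing and new hubs both count toward the quota).  Sub-counties with
    no eligible candidate cannot be covered and are relaxed with a warning.
    """
    covered = {s.sub_county for s in fixed if s.is_hub}
    groups: Dict[str, List[str]] = {}
    relaxed: List[str] = []
    for sc in instance.sub_counties:
        if sc in covered:
            continue
        ids = [c.id for c in cands if c.sub_county == sc]
        if ids:
            groups[sc] = ids
        else:
            relaxed.append(sc)
            logger.warning(
                "fairness: sub-county %s has no eligible candidate hub; "
                "constraint relaxed there",
                sc,
            )
    return groups, relaxed


# ---------------------------------------------------------------------------
# MILP solver
# ---------------------------------------------------------------------------

def solve_allocation(
    instance: ProblemInstance, config: Optional[AllocationConfig] = None
) -> ReferralNetwork:
    """Solve the hub-selection + referral binary program to optimality."""
    if config is None:
        config = AllocationConfig.from_instance(instance)
    fixed, cands = _considered_sites(instance, config)
    p_add = config.n_added_hubs
    if p_add > len(cands):
        raise InfeasibleAllocationError(
            f"requested {p_add} added hubs but only {len(cands)} eligible "
            "candidates exist"
        )
    sites = fixed + cands
    site_ids = [s.id for s in sites]
    try:
        caps = _capacities(instance, config)
    except ValidationError as err:
        raise InfeasibleAllocationError(
            f"capacity constraint class: {err}"
        ) from err
    facilities = instance.facilities
    nf, ns, nc = len(facilities), len(sites), len(cands)
    total_cap = sum(caps[s.id] for s in fixed) + sum(
        sorted((caps[c.id] for c in cands), reverse=True)[:p_add]
    )
    demand = np.array([f.daily_demand for f in facilities])
    if demand.sum() > total_cap + 1e-9:
        raise InfeasibleAllocationError(
            f"total demand {demand.sum():.1f}/day exceeds total open capacity "
            f"{total_cap:.1f}/day (capacity constraint class)"
        )

    tmin = np.array(
        [
            [instance.transport_minutes(f.id, j) for j in site_ids]
            for f in facilities
        ]
    )
    weights = demand if config.demand_weighted else np.ones(nf)
    # variables: x (nf*ns, row-major by facility), then y (nc).  The
    # batching term w_i * B is constant over j (every clinic is assigned
    # exactly once), so it is left out of the solver objective for
    # numerical conditioning and added back in the reported value.
    nx = nf * ns
    c = np.concatenate([(weights[:, None] * tmin).ravel(), np.zeros(nc)])

    rows, cols, vals, lbs, ubs = [], [], [], [], []
    r = 0

    def add_entry(row, col, val):
        rows.append(row)
        cols.append(col)
        vals.append(val)

    # each clinic assigned exactly once
    for i in range(nf):
        for j in range(ns):
            add_entry(r, i * ns + j, 1.0)
        lbs.append(1.0)
        ubs.append(1.0)
        r += 1
    # linking x_ij <= y_j for candidates
    for k, cand in enumerate(cands):
        j = ns - nc + k
        for i in range(nf):
            add_entry(r, i * ns + j, 1.0)
            add_entry(r, nx + k, -1.0)
            lbs.append(-np.inf)
            ubs.append(0.0)
            r += 1
    # capacity
    for j, s in enumerate(sites):
        for i in range(nf):
            if demand[i] > 0:
                add_entry(r, i * ns + j, demand[i])
        if s.fixed_open:
            lbs.append(-np.inf)
            ubs.append(caps[s.id])
        else:
            add_entry(r, nx + (j - (ns - nc)), -caps[s.id])
            lbs.append(-np.inf)
            ubs.append(0.0)
        r += 1
    # number of added hubs
    for k in range(nc):
        add_entry(r, nx + k, 1.0)
    lbs.append(float(p_add))
    ubs.append(float(p_add))
    r += 1
    # fairness
    relaxed: List[str] = []
    if config.fairness and not config.labs_only:
        groups, relaxed = _fairness_groups(instance, fixed, cands)
        if len(groups) > p_add:
            raise InfeasibleAllocationError(
                f"fairness needs >= {len(groups)} new hubs to cover all "
                f"sub-counties but n_added_hubs = {p_add} "
                "(fairness constraint class)"
            )
        cand_index = {cand.id: k for k, cand in enumerate(cands)}
        for sc, ids in groups.items():
            for cid in ids:
                add_entry(r, nx + cand_index[cid], 1.0)
            lbs.append(1.0)
            ubs.append(np.inf)
            r += 1

    # optional sparsification: a clinic may refer only to central labs and
    # its nearest-K hub sites (pruned variables get an upper bound of 0)
    var_ub = np.ones(nx + nc)
    limit = config.nearest_hub_limit
    hub_cols = [j for j, s in enumerate(sites) if s.is_hub]
    if limit is not None and len(hub_cols) > limit:
        for i in range(nf):
            ranked = sorted(hub_cols, key=lambda j: tmin[i, j])
            for j in ranked[limit:]:
                var_ub[i * ns + j] = 0.0

    a_mat = sp.coo_matrix((vals, (rows, cols)), shape=(r, nx + nc)).tocsc()
    res = milp(
        c,
        constraints=LinearConstraint(a_mat, np.array(lbs), np.array(ubs)),
        integrality=np.ones(nx + nc),
        bounds=Bounds(np.zeros(nx + nc), var_ub),
        options={"time_limit": config.time_limit_s, "mip_rel_gap": config.mip_gap},
    )
    if res.status != 0 or res.x is None:
        raise InfeasibleAllocationError(
            f"solver reported no optimal solution (status {res.status}: "
            f"{res.message})"
        )
    x = res.x[:nx].reshape(nf, ns)
    y = res.x[nx:]
    assignment = {
        facilities[i].id: site_ids[int(np.argmax(x[i]))] for i in range(nf)
    }
    open_sites = {s.id for s in fixed}
    open_sites.update(cands[k].id for k in range(nc) if y[k] > 0.5)
    status = "relaxed_fairness" if relaxed else "optimal"
    return ReferralNetwork(
        open_sites=open_sites,
        assignment=assignment,
        objective_value=_objective_value(instance, assignment, config),
        solver_status=status,
        relaxed_sub_counties=relaxed,
    )


# ---------------------------------------------------------------------------
# exhaustive oracle and existing network
# ---------------------------------------------------------------------------

def bruteforce_allocation(
    instance: ProblemInstance, config: Optional[AllocationConfig] = None
) -> ReferralNetwork:
    """Global optimum by exhaustive enumeration (small instances only).

    Enumerates every candidate subset of size ``p_add`` and, per subset,
    every capacity-feasible assignment (depth-first with cost pruning).
    Ties are broken toward lexicographically smaller site ids.  Guard rails:
    at most 8 facilities and 5 candidate sites.
    """
    if config is None:
        config = AllocationConfig.from_instance(instance)
    if len(instance.facilities) > 8 or len(instance.candidate_hubs) > 5:
        raise ValidationError(
            "bruteforce_allocation is limited to <= 8 facilities and "
            "<= 5 candidate sites"
        )
    fixed, cands = _considered_sites(instance, config)
    caps = _capacities(instance, config)
    b = instance.batching.expected_delay_min
    facilities = sorted(
        instance.facilities, key=lambda f: (-f.daily_demand, f.id)
    )
    groups, relaxed = ({}, [])
    if config.fairness:
        groups, relaxed = _fairness_groups(instance, fixed, cands)

    best_cost = np.inf
    best: Optional[tuple] = None
    cand_ids = sorted(c.id for c in cands)
    for subset in itertools.combinations(cand_ids, config.n_added_hubs):
        chosen = set(subset)
        if config.fairness and any(
            not chosen.intersection(ids) for ids in groups.values()
        ):
            continue
        open_ids = sorted({s.id for s in fixed} | chosen)
        cost_ij = {
            (f.id, j): (f.daily_demand if config.demand_weighted else 1.0)
            * (b + instance.transport_minutes(f.id, j))
            for f in facilities
            for j in open_ids
        }
        remaining = {j: caps[j] for j in open_ids}
        assign: Dict[str, str] = {}

        def dfs(idx: int, cost: float) -> None:
            nonlocal best_cost, best
            if cost >= best_cost:
                return
            if idx == len(facilities):
                best_cost = cost
                best = (dict(assign), set(open_ids))
                return
            f = facilities[idx]
            for j in open_ids:
                if remaining[j] + 1e-9 >= f.daily_demand:
                    remaining[j] -= f.daily_demand
                    assign[f.id] = j
                    dfs(idx + 1, cost + cost_ij[(f.id, j)])
                    del assign[f.id]
                    remaining[j] += f.daily_demand

        dfs(0, 0.0)

    if best is None:
        raise InfeasibleAllocationError(
            "no feasible assignment found by enumeration"
        )
    assignment, open_sites = best
    status = "relaxed_fairness" if relaxed else "optimal"
    return ReferralNetwork(
        open_sites=open_sites,
        assignment=assignment,
        objective_value=_objective_value(instance, assignment, config),
        solver_status=status,
        relaxed_sub_counties=list(relaxed),
    )


def existing_network(instance: ProblemInstance) -> ReferralNetwork:
    """The status-quo referral network: central labs only, no optimization.

    Capacity violations are reported as warnings, not errors — the existing
    system may well exceed the planner's utilization cap.
    """
    lab_ids = {lab.id for lab in instance.central_labs}
    config = AllocationConfig.from_instance(instance, n_added_hubs=0)
    assignment = {}
    loads: Dict[str, float] = {lid: 0.0 for lid in lab_ids}
    for f in instance.facilities:
        if f.current_site_id not in lab_ids:
            raise ValidationError(
                f"facility {f.id}: current site {f.current_site_id!r} "
                "is not a central lab"
            )
        assignment[f.id] = f.current_site_id
        loads[f.current_site_id] += f.daily_demand
    warnings = []
    background = baseline_background(instance)
    for lab in instance.central_labs:
        try:
            cap = site_capacity(
                lab,
                background_demand=background[lab.id],
                utilization_cap=instance.utilization_cap,
            )
        except ValidationError:
            cap = 0.0
        if loads[lab.id] > cap:
            msg = (
                f"existing network: lab {lab.id} accepts {loads[lab.id]:.1f}"
                f"/day, above its capped in-county capacity {cap:.1f}/day"
            )
            warnings.append(msg)
            logger.warning(msg)
    return ReferralNetwork(
        open_sites=set(lab_ids),
        assignment=assignment,
        objective_value=_objective_value(instance, assignment, config),
        solver_status="existing",
        warnings=warnings,
    )
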