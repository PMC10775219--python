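"""Steady-state M/M/s machinery for testing sites, plus a simulation oracle.

Every testing site is modelled as a Markovian queue in steady state:

* a POC hub is a single M/M/s queue whose servers are its machines, with the
  per-machine service rate scaled by the fraction of machine time dedicated
  to viral-load testing;
* a central lab is a tandem of two queues — an M/M/s data-entry stage and an
  M/M/1 machine-testing stage — fed by the same total arrival stream
  (in-county referrals plus a constant out-of-county background).  The
  expected time at the lab is the sum of the two stage sojourn times.

All rates are per working day; waits returned here are in working days and
are converted to minutes by the evaluation layer.  ``simulate_mms`` is an
independent event-driven simulator used to validate the analytic formulas.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import TestingSite, ValidationError

__all__ = [
    "UnstableQueueError",
    "QueueSpec",
    "QueueMetrics",
    "SiteLoad",
    "SimulationResult",
    "erlang_c",
    "mms_metrics",
    "central_lab_wait",
    "poc_hub_wait",
    "background_rate",
    "simulate_mms",
]


class UnstableQueueError(RuntimeError):
    """A queue's offered load meets or exceeds its capacity (rho >= 1)."""

    def __init__(self, message: str, utilization: float, stage: Optional[str] = None):
        super().__init__(message)
        self.utilization = utilization
        self.stage = stage


@dataclass(frozen=True)
class QueueSpec:
    """Parameters of one M/M/s queue (rates per working day)."""

    arrival_rate: float  # lambda
    service_rate: float  # mu, per server
    n_servers: int  # s

    def __post_init__(self) -> None:
        if self.arrival_rate < 0:
            raise ValidationError("arrival rate must be non-negative")
        if self.service_rate <= 0:
            raise ValidationError("service rate must be positive")
        if self.n_servers < 1:
            raise ValidationError("need at least one server")

    @property
    def utilization(self) -> float:
        return self.arrival_rate / (self.n_servers * self.service_rate)


@dataclass(frozen=True)
class QueueMetrics:
    """Steady-state performance of one M/M/s queue (times in working days)."""

    utilization: float
    p_wait: float  # Erlang-C probability of delay
    wq: float  # expected wait in queue
    w: float  # expected time in system (wq + 1/mu)
    stable: bool


@dataclass(frozen=True)
class SiteLoad:
    """Arrival streams offered to one testing site (samples/working day)."""

    site_id: str
    assigned_demand: float  # in-county referrals
    background_demand: float = 0.0  # out-of-county (central labs only)

    @property
    def total(self) -> float:
        return self.assigned_demand + self.background_demand


# ---------------------------------------------------------------------------
# analytic formulas
# ---------------------------------------------------------------------------

def erlang_c(arrival_rate: float, service_rate: float, n_servers: int) -> float:
    """Probability an arriving sample must wait in an M/M/s queue.

    Computed via the Erlang-B recurrence ``B_k = a B_{k-1} / (k + a B_{k-1})``
    (with offered load ``a = lambda/mu``) followed by the B-to-C conversion —
    numerically stable for large ``s``, unlike the raw factorial sum.
    """
    spec = QueueSpec(arrival_rate, service_rate, n_servers)
    if spec.arrival_rate == 0:
        return 0.0
    rho = spec.utilization
    if rho >= 1:
        raise UnstableQueueError(
            f"unstable queue: rho = {rho:.4f} >= 1", utilization=rho
        )
    a = arrival_rate / service_rate
    b = 1.0
    for k in range(1, n_servers + 1):
        b = a * b / (k + a * b)
    return b / (1.0 - rho * (1.0 - b))


def mms_metrics(spec: QueueSpec) -> QueueMetrics:
    """Steady-state metrics of an M/M/s queue; instability is encoded, not raised."""
    rho = spec.utilization
    if rho >= 1:
        return QueueMetrics(
            utilization=rho, p_wait=1.0, wq=math.inf, w=math.inf, stable=False
        )
    p_wait = erlang_c(spec.arrival_rate, spec.service_rate, spec.n_servers)
    wq = p_wait / (spec.n_servers * spec.service_rate - spec.arrival_rate)
    return QueueMetrics(
        utilization=rho,
        p_wait=p_wait,
        wq=wq,
        w=wq + 1.0 / spec.service_rate,
        stable=True,
    )


def background_rate(site: TestingSite, baseline_assigned: float) -> float:
    """Out-of-county arrival rate implied by a lab's in-county share.

    If a fraction ``f`` of the lab's intake comes from the county and the
    county sends ``baseline_assigned`` samples/day under the existing
    network, the rest of the country contributes
    ``baseline_assigned * (1 - f) / f``, held constant across scenarios.
    """
    f = site.kisumu_fraction
    if not (0 < f <= 1):
        raise ValidationError(f"site {site.id}: kisumu_fraction must be in (0, 1]")
    if baseline_assigned < 0:
        raise ValidationError("baseline assigned demand must be non-negative")
    return baseline_assigned * (1.0 - f) / f


def central_lab_wait(
    site: TestingSite, load: SiteLoad, pooled_entry_rate: bool = False
) -> float:
    """Expected time in system at a central lab, in working days.

    Sum of the sojourn times of the two tandem stages, both fed at the total
    arrival rate (assigned + background): an M/M/s entry stage and an M/M/1
    machine stage.  ``pooled_entry_rate`` reinterprets the entry rate as a
    lab-level total shared by the servers instead of a per-server rate.
    """
    if not site.is_central_lab:
        raise ValidationError(f"site {site.id} is not a central lab")
    lam = load.total
    entry_mu = site.entry_service_rate
    if pooled_entry_rate:
        entry_mu = entry_mu / site.n_entry_servers
    entry = mms_metrics(QueueSpec(lam, entry_mu, site.n_entry_servers))
    if not entry.stable:
        raise UnstableQueueError(
            f"central lab {site.id}: entry stage unstable "
            f"(rho = {entry.utilization:.3f})",
            utilization=entry.utilization,
            stage="entry",
        )
    machine = mms_metrics(QueueSpec(lam, site.machine_service_rate, 1))
    if not machine.stable:
        raise UnstableQueueError(
            f"central lab {site.id}: machine stage unstable "
            f"(rho = {machine.utilization:.3f})",
            utilization=machine.utilization,
            stage="machine",
        )
    return entry.w + machine.w


def poc_hub_wait(site: TestingSite, load: SiteLoad) -> float:
    """Expected time in system at a POC hub, in working days.

    M/M/s with one server per machine and effective per-machine rate
    ``machine_service_rate * vl_fraction`` (multi-disease platforms dedicate
    only part of their time to VL testing).
    """
    if not site.is_hub:
        raise ValidationError(f"site {site.id} is not a POC hub")
    if load.background_demand != 0:
        raise ValidationError(f"hub {site.id}: hubs have no background stream")
    mu_eff = site.machine_service_rate * site.vl_fraction
    metrics = mms_metrics(QueueSpec(load.total, mu_eff, site.n_machines))
    if not metrics.stable:
        raise UnstableQueueError(
            f"hub {site.id}: unstable (rho = {metrics.utilization:.3f})",
            utilization=metrics.utilization,
        )
    return metrics.w


def site_queue_metrics(
    site: TestingSite, load: SiteLoad, pooled_entry_rate: bool = False
) -> list:
    """Per-stage QueueMetrics for a site (two entries for labs, one for hubs)."""
    lam = load.total
    if site.is_central_lab:
        entry_mu = site.entry_service_rate
        if pooled_entry_rate:
            entry_mu = entry_mu / site.n_entry_servers
        return [
            mms_metrics(QueueSpec(lam, entry_mu, site.n_entry_servers)),
            mms_metrics(QueueSpec(lam, site.machine_service_rate, 1)),
        ]
    mu_eff = site.machine_service_rate * site.vl_fraction
    return [mms_metrics(QueueSpec(lam, mu_eff, site.n_machines))]


# ---------------------------------------------------------------------------
# discrete-event simulation oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationResult:
    """Empirical queue wait from a simulation run (working days)."""

    mean_wq: float
    stderr: float
    n_arrivals: int
    n_used: int  # arrivals kept after warm-up


def simulate_mms(
    spec: QueueSpec,
    n_arrivals: int = 100_000,
    seed: int = 0,
    warmup_fraction: float = 0.1,
    n_batches: int = 20,
) -> SimulationResult:
    """Event-driven simulation of an M/M/s queue.

    Poisson arrivals, exponential service, ``s`` identical servers, FIFO.
    Implemented as a heap of server-free times: an arrival's wait is the
    positive part of (earliest server-free time - arrival time).  The first
    ``warmup_fraction`` of arrivals is discarded and the standard error of
    the mean wait is estimated by batch means; the default batch count is
    deliberately small so batches span several relaxation times even for
    near-critical queues, keeping the error estimate honest.
    """
    if n_arrivals < 10_000:
        raise ValidationError("need at least 10^4 arrivals for a meaningful run")
    if spec.utilization >= 1:
        raise UnstableQueueError(
            "refusing to simulate an unstable queue", utilization=spec.utilization
        )
    if spec.arrival_rate == 0:
        return SimulationResult(0.0, 0.0, n_arrivals, n_arrivals)
    rng = np.random.default_rng(seed)
    arrivals = np.cumsum(rng.exponential(1.0 / spec.arrival_rate, n_arrivals))
    services = rng.exponential(1.0 / spec.service_rate, n_arrivals)
    free = [0.0] * spec.n_servers  # server-free times
    heapq.heapify(free)
    waits = np.empty(n_arrivals)
    for i in range(n_arrivals):
        t = arrivals[i]
        earliest = heapq.heappop(free)
        start = earliest if earliest > t else t
        waits[i] = start - t
        heapq.heappush(free, start + services[i])
    kept = waits[int(warmup_fraction * n_arrivals):]
    usable = len(kept) - len(kept) % n_batches
    batches = kept[:usable].reshape(n_batches, -1).mean(axis=1)
    stderr = float(batches.std(ddof=1) / math.sqrt(n_batches))
    return SimulationResult(float(kept.mean()), stderr, n_arrivals, len(kept))
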