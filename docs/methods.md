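# Methods

## Model

A county VL testing system is a bipartite network of clinics (demand) and
testing sites (service). Expected turnaround time per sample from one
clinic is

    TAT = B + t(clinic, site) + W(site)

with all terms in minutes.

**Demand.** Annual testing demand per clinic is `2 × child volume + 1.08 ×
adult volume` (children are tested twice yearly; adults average 1.08 tests
per year under current guidelines), converted to samples per working day
at 20 workdays per month. Demand is kept fractional — the model is a
steady-state fluid approximation, so capacities are compared against
fractional rates, and zero-demand clinics stay in the instance (they are
assigned a site and count toward facility-level means, with zero weight in
system totals).

**Batching delay `B`.** Dispatch frequency determines the expected wait at
the clinic under a uniform-arrival assumption: half a working day for
daily dispatch; one calendar day plus a workday for twice-weekly; half the
four-day-plus-one-workday span for once-weekly. With the default 7-hour
working day these give 210, 1860 and 3090 minutes. The workday length is
configurable; the standard values are recovered at 7 h.

**Transport `t`.** `distance / speed × road_coeff × weather_coeff`, one
mode per run (the data do not distinguish per-leg modes). Default speeds:
walk 5, bike 20, motorbike 40, car 50 km/h; condition multipliers 0.8
(good), 1.0 (average), 1.2 (bad). A travel-time matrix, when supplied,
overrides the speed computation.

**Waiting `W`.** Steady-state M/M/s expectations, rates per working day:

* POC hub: s = machine count, per-server rate = 12 × `vl_fraction`. The
  multi-disease nature of the platform is modelled as a capacity share
  (`vl_fraction` of machine time dedicated to VL), not as competing
  arrival streams — the data expose only a dedication proportion.
* Central lab: tandem of an M/M/s entry stage (servers = data clerks, 710
  samples/day per clerk) and an M/M/1 machine stage (1500 samples/day),
  both loaded at in-county referrals plus a constant out-of-county
  background; expected time in system is the sum of the two stage sojourn
  times. The 710/day figure is read as a per-server rate (the printed
  server count and rate are listed separately); a `pooled_entry_rate`
  switch reinterprets it as a lab-level total. The machine stage is
  parameterized by its aggregate rate; internal batch mechanics (samples
  racked in groups of 90) are not modelled.
* The background stream is inferred from each lab's in-county sample
  share f: `background = assigned × (1 − f) / f`, where `assigned` is the
  lab's in-county intake under the existing network. It is held constant
  across scenarios — other counties do not re-route when this county does.

Erlang-C is computed by the Erlang-B recurrence plus B-to-C conversion
(stable to s ≫ 50; raw factorial sums appear only in the test oracles).
Waits convert to clock time at 7 working hours per day; reported "hours"
are working hours, since the data give no calendar-time convention.
Instability (utilization ≥ 1) raises a structured error naming the stage;
utilization above the 90% planning cap but below 1 is reported with a
warning, since user-edited or status-quo networks may legitimately exceed
the planner's cap.

## Optimization

Binary variables: `y_j` (open candidate hub j) and `x_ij` (clinic i refers
to site j). Objective: `min Σ_i d_i (B + t_ij) x_ij` — demand-weighted
batching plus transport (an unweighted mode is available). Waiting time is
excluded from the objective and added post hoc: including M/M/s waits
would make the program nonlinear, and waiting is a small fraction of TAT,
so the solution is near-optimal with a pure binary linear model.
Constraints: single assignment; `x_ij ≤ y_j`; `Σ_i d_i x_ij ≤ cap_j y_j`
(big-M-free — the capacity is its own natural bound); `Σ y_j = p_add` over
candidates, with central labs and existing hubs forced open; optional
fairness: every sub-county contains at least one hub (existing hubs count
toward the quota; a sub-county with no eligible candidate is relaxed with
a warning and flagged in the solver status). Site capacity at the cap:
hubs `machines × 12 × vl_fraction × 0.9`; labs `0.9 × min(entry capacity,
machine rate) − background`. Candidate hubs must sit at level-3+
facilities (health centres and above can host the platform).

Scenario 1 deliberately evaluates the *existing* referral network rather
than an optimized labs-only network (a config flag provides the optimized
variant); scenario 2 is the optimized network over labs + existing hubs;
scenario 3 adds `p_add ∈ 0..7` new hubs (`p_add = 0` reduces exactly to
scenario 2).

### Numerical choices

The solver backend is HiGHS (`scipy.optimize.milp`). The batching term is
constant over sites for each clinic (`Σ_j x_ij = 1`), so it is dropped
from the solver objective and restored in the reported value — carrying a
~7.9 × 10^5 constant against decision-relevant differences of order 1
wrecks relative-gap termination. Production defaults: relative MIP gap
1e-3 and referral choices pruned to each clinic's 8 nearest hub sites
(central labs always allowed). County-scale instances make the capacity
packing around a saturated lab genuinely hard to prove optimal — the
LP/IP gap is real, not a formulation artifact — and a 0.1% transport-time
gap is far below any quantity interpreted here. Both settings are
configurable; exact mode (`mip_gap=0`, `nearest_hub_limit=None`) is used
by the tests that compare the solver against exhaustive enumeration on
small instances, where it equals the enumerated optimum on every seeded
case. Tie-breaking among equal-cost optima is solver-determined; the
enumeration oracle breaks ties toward lexicographically smaller site ids,
and cross-checks compare objective values, not assignments.

Infeasibility is diagnosed before and after solving: demand above total
open capacity, more requested hubs than eligible candidates, and fairness
quotas exceeding `p_add` each raise a structured error naming the binding
constraint class.

## Evaluation and sensitivity

`evaluate_network` recomputes every open site's arrival rate from the
assignment (plus lab background), evaluates the queues, and assembles the
per-clinic decomposition. All clinics assigned to a site share its
expected wait. Reported summaries: unweighted mean and SD of TAT across
all clinics (including zero-demand ones); cumulative system time
`Σ_i d_i × TAT_i / 60` in sample-hours per working day (the only
self-consistent demand-weighted reading of a "total time in system"
metric); demand-weighted component shares, which sum to 1 within 1e-9.

The one-way sweep re-solves and re-evaluates each scenario per setting:
central-lab capacity ×1.25/×1.5, ±machines at existing and added hubs,
transport modes, road/weather levels, batching modes — against the
baseline of twice-weekly batching, motorbike, average conditions, with
scenario 3 at 7 added hubs under fairness. Failures of individual runs
are recorded in the output and do not abort the sweep.

## Discrete-event validation

`simulate_mms` is an independent event-driven M/M/s simulator (heap of
server-free times; an arrival's wait is the positive part of the earliest
free time minus the arrival time). The first 10% of arrivals is discarded
as warm-up and the standard error of the mean wait uses batch means with
20 batches — few, long batches keep the estimate honest under the strong
autocorrelation of heavily loaded queues. Cross-checks run a ≥10-point
(λ, μ, s) grid spanning utilizations 0.04–0.96 and require agreement
within 3 standard errors; the heavily loaded points use 10^6 arrivals
because near criticality the sample-mean distribution is still visibly
skewed at 10^5 and a symmetric 3-SE band over-rejects.

## Synthetic county generator

The generator emulates the *structure* of a western-Kenya county VL
system; no real facility data are included. Defaults and rationale:

* **146 clinics, 7 sub-counties**, coordinates clustered around
  sub-county centres inside a Winam-gulf-like bounding box; facility
  levels drawn from a distribution concentrated on levels 2–3.
* **Urban demand gradient.** Raw lognormal clinic volumes are damped by
  `exp(−d/12 km)` with distance from the in-county lab, which sits in the
  county capital (the sub-county nearest the lake-shore corner). Client
  volume in such systems concentrates heavily in the urban centre; the
  gradient also gives new peripheral hubs realistic, moderate catchments.
  About 5% of clinics have zero demand; per-clinic daily demand spans
  [0, 37].
* **Labs.** One in-county reference lab plus two labs 90–130 km away
  (bearing NE and SE), all with the standard two-stage parameters and
  in-county shares 24%, 13%, 5%. Per-lab in-county intake is calibrated
  via entry-stage utilization targets (0.9975, 0.10, 0.12) under the
  existing network: the reference lab runs essentially at saturation —
  the regime documented for the system this emulates, where demand
  roughly equals the lab's adjusted capacity — while the distant labs are
  dominated by their own out-of-county work. Clinic volumes are scaled
  group-wise (by current lab) to hit these targets, then converted to
  integer child/adult volumes (children ≈ 10% of adults) and re-derived,
  with a mid-size clinic absorbing the rounding drift so the saturated
  lab stays strictly stable.
* **Existing network.** Clinics use their nearest lab except for a 20%
  misrouted share drawn from the smaller clinics (large hospitals have
  established courier relationships; the misrouted stream is what feeds
  the distant labs' in-county intake).
* **Hubs.** The 7 existing hubs sit at the county's highest-volume
  hospitals with machine counts {4, 2, 1, 1, 1, 1, 1} matched to volume
  rank, and host demand pinned at 88% of the hub's own VL capacity —
  machine counts were sized to their hospital's caseload. The 12
  candidate sites are chosen by coverage gap: within each sub-county the
  level-3+ clinic farthest from every existing testing site, then the
  globally least-covered eligible clinics (a sub-county with no level-3+
  clinic has its busiest clinic promoted, keeping the fairness constraint
  feasible by construction). Candidates carry 2 machines, the convention
  for newly added hubs.
* **Distances.** Great-circle × 1.3 circuity, the standard road-network
  approximation; generation fails loudly if total demand exceeds total
  capped capacity or any lab would be unstable under the existing
  network.

What the generator does *not* emulate: real road networks (circuity is a
single factor), seasonal demand, machine downtime, and the actual Kisumu
facility registry. Passing tests on this county therefore demonstrate the
model's internal correctness and the direction and rough magnitude of the
policy effects (hubs reduce TAT; batching frequency dominates; transport
conditions are second-order), not county-specific point estimates. The
canonical packaged instance is seed 1; most seeds reproduce the full
scenario ordering, while occasionally an unusually good scenario-2
network leaves scenario 3 marginally behind — the same "nearly monotone"
behaviour reported for the real system.

## Known limitations

* Markovian service and arrivals; no priority classes, downtime, or
  non-exponential service.
* Waiting time is evaluated, not optimized; networks can therefore show
  small waiting regressions as hubs are added even as batching+transport
  strictly improves.
* Calendar-time effects of batching (weekend accumulation changing
  arrival patterns) are ignored; arrival rates are dispatch-mode
  independent.
* The background streams at central labs are constants, not decision
  variables — a national-scale model would re-balance them.
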