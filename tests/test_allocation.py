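import pytest

import pocplan as p
from pocplan.allocation import (
    AllocationConfig,
    InfeasibleAllocationError,
    baseline_background,
    bruteforce_allocation,
    eligible_candidates,
    existing_network,
    site_capacity,
    solve_allocation,
)

EXACT = dict(mip_gap=0.0, nearest_hub_limit=None)


def _site(kind="candidate_hub", level=3, **kw):
    base = dict(
        id="S", name="s", kind=kind, sub_county="X", lat=0, lon=0,
        machine_service_rate=12, n_machines=1, vl_fraction=1.0,
        fixed_open=kind != "candidate_hub", level=level,
    )
    base.update(kw)
    return p.TestingSite(**base)


class TestEligibility:
    def test_levels_three_to_five_qualify(self):
        config = AllocationConfig()
        sites = [_site(id="C2", level=2), _site(id="C3", level=3),
                 _site(id="C5", level=5)]
        for s, want in zip(sites, (False, True, True)):
            assert (s.id in eligible_candidates(sites, config)) == want

    def test_fixed_sites_pass_unconditionally(self):
        hub = _site(id="H1", kind="existing_hub", level=2)
        assert eligible_candidates([hub], AllocationConfig()) == ["H1"]

    def test_empty_input(self):
        assert eligible_candidates([], AllocationConfig()) == []


class TestSiteCapacity:
    def test_hub_capacity(self):
        hub = _site(kind="existing_hub", n_machines=2)
        assert site_capacity(hub, utilization_cap=0.9) == pytest.approx(21.6)
        half = _site(kind="existing_hub", n_machines=1, vl_fraction=0.5)
        assert site_capacity(half, utilization_cap=0.9) == pytest.approx(5.4)

    def test_central_lab_bottleneck_minus_background(self):
        lab = p.TestingSite(
            id="L", name="l", kind="central_lab", sub_county="X", lat=0, lon=0,
            machine_service_rate=1500, n_machines=1, n_entry_servers=2,
            entry_service_rate=710, kisumu_fraction=0.24, fixed_open=True,
        )
        cap = site_capacity(lab, background_demand=1000, utilization_cap=0.9)
        assert cap == pytest.approx(0.9 * min(2 * 710, 1500) - 1000)  # 278
        with pytest.raises(p.ValidationError):
            site_capacity(lab, background_demand=1300, utilization_cap=0.9)


class TestExistingNetwork:
    def test_uses_current_sites_and_opens_labs_only(self, small_instance):
        net = existing_network(small_instance)
        labs = {s.id for s in small_instance.central_labs}
        assert net.open_sites == labs
        for f in small_instance.facilities:
            assert net.assignment[f.id] == f.current_site_id

    def test_capacity_violation_warns_not_raises(self):
        inst = p.make_fixture_small(seed=3)
        for f in inst.facilities:  # inflate demand well past the lab caps
            f.annual_adult_volume = 3000
            f.__post_init__()
        net = existing_network(inst)
        assert net.warnings  # reported, not raised


class TestSolveAllocation:
    def test_single_facility_assigned_to_open_lab(self, small_instance):
        inst = small_instance
        f = inst.facilities[0]
        one = p.ProblemInstance(
            facilities=[f],
            sites=[s for s in inst.sites if s.kind == "central_lab"],
            distance_km=inst.distance_km,
            transport=inst.transport,
            batching=inst.batching,
        )
        net = solve_allocation(one, AllocationConfig(**EXACT))
        sid = net.assignment[f.id]
        b = one.batching.expected_delay_min
        expected = f.daily_demand * (b + one.transport_minutes(f.id, sid))
        assert net.objective_value == pytest.approx(expected)

    def test_nonbinding_capacity_gives_nearest_site(self, small_instance):
        inst = small_instance
        for f in inst.facilities:  # shrink demand so no capacity can bind
            f.annual_adult_volume = max(1, int(f.annual_adult_volume * 0.05))
            f.__post_init__()
        net = solve_allocation(inst, AllocationConfig(n_added_hubs=0, **EXACT))
        for f in inst.facilities:
            best = min(
                (s.id for s in inst.sites if s.fixed_open),
                key=lambda j: (inst.transport_minutes(f.id, j), j),
            )
            assert inst.transport_minutes(f.id, net.assignment[f.id]) == (
                pytest.approx(inst.transport_minutes(f.id, best))
            )

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_on_small_instances(self, seed):
        inst = p.make_fixture_small(seed)
        pa = seed % 3
        config = AllocationConfig(
            n_added_hubs=pa, fairness=bool(seed % 2) and pa >= 1, **EXACT
        )
        a = solve_allocation(inst, config)
        b = bruteforce_allocation(inst, config)
        assert a.objective_value == pytest.approx(b.objective_value, abs=1e-6)
        assert len(a.open_sites) == len(b.open_sites)

    def test_network_invariants(self, small_instance):
        config = AllocationConfig(n_added_hubs=2, **EXACT)
        net = solve_allocation(small_instance, config)
        fac_ids = {f.id for f in small_instance.facilities}
        assert set(net.assignment) == fac_ids
        assert set(net.assignment.values()) <= net.open_sites
        fixed = {s.id for s in small_instance.sites if s.fixed_open}
        assert fixed <= net.open_sites
        cands = net.open_sites - fixed
        assert len(cands) == 2
        # capacity respected at the utilization cap
        background = baseline_background(small_instance)
        loads = {sid: 0.0 for sid in net.open_sites}
        for f in small_instance.facilities:
            loads[net.assignment[f.id]] += f.daily_demand
        for s in small_instance.sites:
            if s.id in net.open_sites:
                cap = site_capacity(s, background.get(s.id, 0.0), 0.9)
                assert loads[s.id] <= cap + 1e-6

    def test_fairness_never_cheaper(self):
        inst = p.make_fixture_small(seed=5)
        off = solve_allocation(inst, AllocationConfig(n_added_hubs=2, **EXACT))
        on = solve_allocation(
            inst, AllocationConfig(n_added_hubs=2, fairness=True, **EXACT)
        )
        assert on.objective_value >= off.objective_value - 1e-9

    def test_fairness_relaxed_when_no_candidate_in_subcounty(self, small_instance):
        inst = small_instance
        # strand one sub-county: no hub and no eligible candidate there
        for f in inst.facilities[:2]:
            f.sub_county = "Z"
        net = solve_allocation(
            inst, AllocationConfig(n_added_hubs=1, fairness=True, **EXACT)
        )
        assert net.solver_status == "relaxed_fairness"
        assert "Z" in net.relaxed_sub_counties

    def test_impossible_hub_count_is_structured_error(self, small_instance):
        with pytest.raises(InfeasibleAllocationError):
            solve_allocation(
                small_instance, AllocationConfig(n_added_hubs=3 + 1, **EXACT)
            )

    def test_demand_exceeding_capacity_is_structured_error(self, small_instance):
        inst = small_instance
        for f in inst.facilities:
            f.annual_adult_volume = 50_000
            f.__post_init__()
        with pytest.raises(InfeasibleAllocationError) as err:
            solve_allocation(inst, AllocationConfig(n_added_hubs=0, **EXACT))
        assert "capacity" in str(err.value)


class TestBruteforce:
    def test_guard_rails(self, county):
        with pytest.raises(p.ValidationError):
            bruteforce_allocation(county, AllocationConfig())

    def test_all_candidates_open_when_p_equals_count(self, small_instance):
        config = AllocationConfig(n_added_hubs=3, **EXACT)
        net = bruteforce_allocation(small_instance, config)
        cands = {s.id for s in small_instance.candidate_hubs}
        assert cands <= net.open_sites

    def test_optimum_beats_every_alternative_assignment(self, small_instance):
        config = AllocationConfig(n_added_hubs=0, **EXACT)
        net = bruteforce_allocation(small_instance, config)
        b = small_instance.batching.expected_delay_min
        # swapping any single facility to another open site cannot improve
        for f in small_instance.facilities:
            for sid in net.open_sites:
                alt = dict(net.assignment)
                alt[f.id] = sid
                cost = sum(
                    small_instance.facility_by_id[i].daily_demand
                    * (b + small_instance.transport_minutes(i, j))
                    for i, j in alt.items()
                )
                assert cost >= net.objective_value - 1e-9
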