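import copy

import numpy as np
import pytest

import pocplan as p
from pocplan.evaluation import default_sensitivity_grid, sensitivity_sweep


class TestDecomposition:
    def test_tat_is_exactly_additive(self, scenario_reports):
        for report in scenario_reports.values():
            for t in report.facility_tats:
                assert t.total_min == t.batching_min + t.transport_min + t.waiting_min
            assert sum(report.component_shares.values()) == pytest.approx(
                1.0, abs=1e-9
            )

    def test_single_clinic_composition(self):
        inst = p.make_fixture_small(seed=0)
        net = p.existing_network(inst)
        report = p.evaluate_network(inst, net)
        f = inst.facilities[0]
        t = next(x for x in report.facility_tats if x.facility_id == f.id)
        assert t.batching_min == inst.batching.expected_delay_min
        assert t.transport_min == pytest.approx(
            inst.transport_minutes(f.id, f.current_site_id)
        )
        assert t.waiting_min > 0

    def test_zero_demand_clinic_counts_in_mean_not_in_hours(self):
        inst = p.make_fixture_small(seed=0)
        zero = [f for f in inst.facilities if f.daily_demand == 0]
        assert zero  # the fixture keeps one zero-demand clinic
        report = p.evaluate_network(inst, p.existing_network(inst))
        totals = [t.total_min for t in report.facility_tats]
        assert report.mean_tat_min == pytest.approx(np.mean(totals))
        assert len(totals) == len(inst.facilities)
        weighted = sum(
            inst.facility_by_id[t.facility_id].daily_demand * t.total_min
            for t in report.facility_tats
        )
        assert report.total_sample_hours == pytest.approx(weighted / 60.0)

    def test_same_site_same_waiting(self, scenario_reports):
        report = scenario_reports[2]
        by_site = {}
        for t in report.facility_tats:
            by_site.setdefault(t.site_id, set()).add(t.waiting_min)
        for waits in by_site.values():
            assert len(waits) == 1

    def test_assignment_to_closed_site_rejected(self):
        inst = p.make_fixture_small(seed=0)
        net = p.existing_network(inst)
        net.assignment[inst.facilities[0].id] = "C1"  # C1 is not open
        with pytest.raises(p.ValidationError):
            p.evaluate_network(inst, net)


class TestScenarios:
    def test_scenario_labels(self, scenario_reports):
        assert scenario_reports[1].scenario == "scenario_1"
        assert scenario_reports[2].scenario == "scenario_2"
        assert scenario_reports[3].scenario == "scenario_3_p7"

    def test_scenario_one_is_existing_network(self, county, scenario_reports):
        for f in county.facilities:
            assert scenario_reports[1].network.assignment[f.id] == f.current_site_id

    def test_scenario_three_with_no_added_hubs_equals_scenario_two(self, county):
        r2 = p.run_scenario(county, 2)
        r3 = p.run_scenario(county, 3, p_add=0)
        assert r3.network.assignment == r2.network.assignment
        assert r3.mean_tat_min == pytest.approx(r2.mean_tat_min)

    def test_adding_hubs_shrinks_waiting_share(self, scenario_reports):
        # hub roll-out shifts the system from queue-bound to batching-bound
        assert (
            scenario_reports[2].component_shares["waiting"]
            < scenario_reports[1].component_shares["waiting"]
        )

    def test_invalid_scenario_rejected(self, county):
        with pytest.raises(p.ValidationError):
            p.run_scenario(county, 4)
        with pytest.raises(p.ValidationError):
            p.run_scenario(county, 3, p_add=9)


class TestComponentIsolation:
    def test_batching_mode_changes_only_batching(self):
        inst = p.make_fixture_small(seed=1)
        net = p.existing_network(inst)
        base = p.evaluate_network(inst, net)
        fast = copy.deepcopy(inst)
        fast.batching = p.BatchingPolicy("daily")
        daily = p.evaluate_network(fast, net)
        for a, b in zip(base.facility_tats, daily.facility_tats):
            assert b.batching_min == 210.0 and a.batching_min == 1860.0
            assert b.transport_min == a.transport_min
            assert b.waiting_min == a.waiting_min

    def test_transport_mode_changes_only_transport(self):
        inst = p.make_fixture_small(seed=1)
        net = p.existing_network(inst)
        base = p.evaluate_network(inst, net)
        slow = copy.deepcopy(inst)
        slow.transport = p.TransportParams("walk")
        walk = p.evaluate_network(slow, net)
        for a, b in zip(base.facility_tats, walk.facility_tats):
            assert b.batching_min == a.batching_min
            assert b.waiting_min == a.waiting_min
            if a.transport_min > 0:
                assert b.transport_min == pytest.approx(8 * a.transport_min)

    def test_faster_service_weakly_reduces_waits(self):
        inst = p.make_fixture_small(seed=1)
        net = p.existing_network(inst)
        base = p.evaluate_network(inst, net)
        boosted = copy.deepcopy(inst)
        for s in boosted.sites:
            s.entry_service_rate *= 1.5
            s.machine_service_rate *= 1.5
        better = p.evaluate_network(boosted, net)
        for a, b in zip(base.facility_tats, better.facility_tats):
            assert b.waiting_min <= a.waiting_min + 1e-12


class TestSensitivity:
    def test_sweep_reports_every_cell_and_baselines(self):
        inst = p.make_fixture_small(seed=2)
        grid = [g for g in default_sensitivity_grid() if g[0] == "batching_mode"]
        results = sensitivity_sweep(inst, grid=grid, scenarios=(1, 2), p_add=1)
        assert len(results) == 2 + len(grid) * 2  # baselines + cells
        base = [r for r in results if r.parameter == "baseline"]
        assert all(r.percent_change_vs_baseline == 0 for r in base)

    def test_batching_dominates_percent_changes(self):
        inst = p.make_fixture_small(seed=2)
        grid = [
            g
            for g in default_sensitivity_grid()
            if g[0] in ("batching_mode", "road_condition")
        ]
        results = sensitivity_sweep(inst, grid=grid, scenarios=(1,), p_add=1)
        changes = {
            (r.parameter, r.setting): r.percent_change_vs_baseline
            for r in results
            if r.parameter != "baseline"
        }
        assert changes[("batching_mode", "daily")] < -50
        assert changes[("batching_mode", "once_weekly")] > 0
        assert abs(changes[("road_condition", "good")]) < abs(
            changes[("batching_mode", "daily")]
        )

    def test_failures_recorded_not_raised(self):
        inst = p.make_fixture_small(seed=2)

        def explode(instance):
            raise RuntimeError("boom")

        results = sensitivity_sweep(
            inst, grid=[("broken", "x", explode)], scenarios=(1,), p_add=1
        )
        broken = [r for r in results if r.parameter == "broken"]
        assert len(broken) == 1 and broken[0].status.startswith("failed")
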