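import math

import pytest

from pocplan import (
    QueueSpec,
    SiteLoad,
    TestingSite,
    UnstableQueueError,
    ValidationError,
    background_rate,
    central_lab_wait,
    erlang_c,
    mms_metrics,
    poc_hub_wait,
    simulate_mms,
)

from oracles import erlang_c_direct, mm1_wq, mms_wq_direct

GRID = [
    (1.0, 2.0, 1), (0.5, 1.0, 1), (5.0, 2.0, 3), (10.0, 4.0, 3),
    (8.0, 1.0, 10), (20.0, 12.0, 2), (45.0, 12.0, 5), (9.0, 12.0, 1),
    (680.0, 710.0, 1), (1300.0, 710.0, 2), (30.0, 0.7, 50), (3.3, 0.1, 40),
]


def _lab(**kw):
    base = dict(
        id="L", name="lab", kind="central_lab", sub_county="X", lat=0, lon=0,
        machine_service_rate=1500, n_machines=1, n_entry_servers=2,
        entry_service_rate=710, kisumu_fraction=0.24, fixed_open=True,
    )
    base.update(kw)
    return TestingSite(**base)


def _hub(**kw):
    base = dict(
        id="H", name="hub", kind="existing_hub", sub_county="X", lat=0, lon=0,
        machine_service_rate=12, n_machines=1, vl_fraction=1.0,
        fixed_open=True,
    )
    base.update(kw)
    return TestingSite(**base)


class TestErlangC:
    def test_empty_system_never_waits(self):
        assert erlang_c(0, 2.0, 3) == 0.0

    def test_single_server_equals_utilization(self):
        assert erlang_c(1, 2, 1) == pytest.approx(0.5)
        assert erlang_c(3, 4, 1) == pytest.approx(0.75)

    @pytest.mark.parametrize("lam,mu,s", GRID)
    def test_matches_direct_factorial_sum(self, lam, mu, s):
        assert erlang_c(lam, mu, s) == pytest.approx(
            erlang_c_direct(lam, mu, s), rel=1e-12
        )

    def test_unstable_raises_with_utilization(self):
        with pytest.raises(UnstableQueueError) as err:
            erlang_c(10, 2, 3)
        assert err.value.utilization == pytest.approx(10 / 6)


class TestMMsMetrics:
    def test_mm1_closed_form(self):
        m = mms_metrics(QueueSpec(1, 2, 1))
        assert m.wq == pytest.approx(mm1_wq(1, 2))
        assert m.w == pytest.approx(m.wq + 0.5)

    def test_zero_arrivals(self):
        m = mms_metrics(QueueSpec(0, 4, 2))
        assert m.wq == 0 and m.w == pytest.approx(0.25) and m.p_wait == 0

    def test_instability_encoded_not_raised(self):
        m = mms_metrics(QueueSpec(9, 2, 4))
        assert not m.stable and math.isinf(m.wq) and math.isinf(m.w)

    @pytest.mark.parametrize("lam,mu,s", GRID)
    def test_wq_matches_direct_form(self, lam, mu, s):
        assert mms_metrics(QueueSpec(lam, mu, s)).wq == pytest.approx(
            mms_wq_direct(lam, mu, s), rel=1e-12
        )

    def test_wait_monotone_in_load_servers_and_rate(self):
        base = mms_metrics(QueueSpec(10, 4, 3)).wq
        assert mms_metrics(QueueSpec(11, 4, 3)).wq > base
        assert mms_metrics(QueueSpec(10, 4, 4)).wq < base
        assert mms_metrics(QueueSpec(10, 5, 3)).wq < base


class TestSiteWaits:
    def test_central_lab_zero_arrivals_is_sum_of_service_times(self):
        lab = _lab()
        w = central_lab_wait(lab, SiteLoad("L", 0.0, 0.0))
        assert w == pytest.approx(1 / 710 + 1 / 1500)

    def test_central_lab_is_sum_of_two_stages(self):
        lab = _lab()
        lam = 600.0
        w = central_lab_wait(lab, SiteLoad("L", 400.0, 200.0))
        expected = (
            mms_metrics(QueueSpec(lam, 710, 2)).w
            + mms_metrics(QueueSpec(lam, 1500, 1)).w
        )
        assert w == pytest.approx(expected, rel=1e-12)

    def test_entry_stage_instability_identified(self):
        with pytest.raises(UnstableQueueError) as err:
            central_lab_wait(_lab(), SiteLoad("L", 1000.0, 420.0))
        assert err.value.stage == "entry"

    def test_machine_stage_instability_identified(self):
        lab = _lab(machine_service_rate=900.0)
        with pytest.raises(UnstableQueueError) as err:
            central_lab_wait(lab, SiteLoad("L", 500.0, 500.0))
        assert err.value.stage == "machine"

    def test_pooled_entry_rate_reading(self):
        lab = _lab()
        w = central_lab_wait(lab, SiteLoad("L", 300.0, 0.0), pooled_entry_rate=True)
        expected = (
            mms_metrics(QueueSpec(300, 355, 2)).w
            + mms_metrics(QueueSpec(300, 1500, 1)).w
        )
        assert w == pytest.approx(expected)

    def test_hub_single_machine_closed_form(self):
        w = poc_hub_wait(_hub(), SiteLoad("H", 6.0))
        assert w == pytest.approx(1 / (12 - 6))

    def test_hub_vl_share_scales_service(self):
        hub = _hub(n_machines=2, vl_fraction=0.5)
        w = poc_hub_wait(hub, SiteLoad("H", 10.0))
        assert w == pytest.approx(mms_metrics(QueueSpec(10, 6, 2)).w)

    def test_hub_full_dedication_equals_plain_mms(self):
        hub = _hub(n_machines=3)
        w = poc_hub_wait(hub, SiteLoad("H", 20.0))
        assert w == pytest.approx(mms_metrics(QueueSpec(20, 12, 3)).w, rel=1e-12)

    def test_hub_zero_arrivals_is_service_time(self):
        hub = _hub(vl_fraction=0.5)
        assert poc_hub_wait(hub, SiteLoad("H", 0.0)) == pytest.approx(1 / 6)


class TestBackgroundRate:
    def test_all_in_county_means_no_background(self):
        assert background_rate(_lab(kisumu_fraction=1.0), 50.0) == 0.0

    @pytest.mark.parametrize(
        "frac,assigned,expected", [(0.24, 24, 76.0), (0.05, 5, 95.0), (0.13, 13, 87.0)]
    )
    def test_share_arithmetic(self, frac, assigned, expected):
        lab = _lab(kisumu_fraction=frac)
        assert background_rate(lab, assigned) == pytest.approx(expected)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValidationError):
            _lab(kisumu_fraction=0.0)


class TestSimulationOracle:
    def test_mm1_target(self):
        spec = QueueSpec(1, 2, 1)
        res = simulate_mms(spec, n_arrivals=100_000, seed=1)
        assert abs(res.mean_wq - 0.5) <= 3 * res.stderr

    def test_light_traffic_waits_vanish(self):
        res = simulate_mms(QueueSpec(0.001, 1, 4), n_arrivals=10_000, seed=1)
        assert res.mean_wq == pytest.approx(0.0, abs=1e-6)

    def test_reproducible_under_seed(self):
        a = simulate_mms(QueueSpec(10, 4, 3), n_arrivals=20_000, seed=42)
        b = simulate_mms(QueueSpec(10, 4, 3), n_arrivals=20_000, seed=42)
        assert a == b

    def test_agrees_with_analytic(self):
        spec = QueueSpec(10, 4, 3)
        res = simulate_mms(spec, n_arrivals=100_000, seed=7)
        assert abs(res.mean_wq - mms_metrics(spec).wq) <= 3 * res.stderr

    def test_refuses_unstable_or_tiny_runs(self):
        with pytest.raises(UnstableQueueError):
            simulate_mms(QueueSpec(10, 2, 3), n_arrivals=10_000, seed=0)
        with pytest.raises(ValidationError):
            simulate_mms(QueueSpec(1, 2, 1), n_arrivals=100, seed=0)
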