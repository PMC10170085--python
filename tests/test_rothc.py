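"""Unit and property tests for the five-pool turnover engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socbackcast import rothc
from socbackcast.rothc import (
    ForcingSeries,
    LandUse,
    MoistureState,
    MonthlyForcing,
    PoolState,
    RateModifiers,
    SoilParams,
)


def make_forcing(a=1.0, b=1.0, c=1.0, temp=10.0, precip=50.0, pet=40.0, covered=True):
    return MonthlyForcing(temp, precip, pet, covered, RateModifiers(a, b, c))


class TestTemperatureFactor:
    @pytest.mark.parametrize(
        "temp, expected",
        [
            (-18.27, 0.0),
            (-30.0, 0.0),
            (9.25, 0.9944404731497349),  # 47.91/(1+exp(106.06/27.52))
        ],
    )
    def test_values(self, temp, expected):
        assert rothc.temperature_factor(temp) == pytest.approx(expected, abs=1e-12)

    def test_monotone_and_bounded(self):
        temps = np.linspace(-18.0, 60.0, 200)
        a = rothc.temperature_factor(temps)
        assert np.all(np.diff(a) > 0)
        assert np.all(a >= 0)
        assert np.all(a < 47.91 / 2.0)  # supremum of the logistic


class TestMoisture:
    def test_max_deficit_values(self, arable_soil):
        soil23 = SoilParams(clay=8.0, depth=23.0)
        assert rothc.max_deficit(soil23) == pytest.approx(29.76, abs=1e-10)
        assert rothc.max_deficit(soil23, covered=False) == pytest.approx(29.76 / 1.8)
        zero_clay = SoilParams(clay=0.0, depth=23.0)
        assert rothc.max_deficit(zero_clay) == pytest.approx(20.0)
        # 30 cm default scales the 23 cm capacity
        assert rothc.max_deficit(arable_soil) == pytest.approx(29.76 * 30 / 23)

    def test_wet_month_keeps_b_at_one(self, arable_soil):
        cap = rothc.max_deficit(arable_soil)
        state = MoistureState(acc_tsmd=0.0, max_tsmd=cap)
        mods, new = rothc.rate_modifiers(10.0, 60.0, 40.0, True, state, arable_soil)
        assert mods.b == 1.0
        assert new.acc_tsmd == 0.0

    def test_deficit_accumulates_and_b_declines(self, arable_soil):
        cap = rothc.max_deficit(arable_soil)
        state = MoistureState(acc_tsmd=0.0, max_tsmd=cap)
        b_seq = []
        for _ in range(12):  # dry months: precip 0, pet 8 (deficit +6 mm/month)
            mods, state = rothc.rate_modifiers(20.0, 0.0, 8.0, True, state, arable_soil)
            b_seq.append(mods.b)
        assert state.acc_tsmd == pytest.approx(cap)
        assert b_seq[0] == 1.0
        assert b_seq[-1] == pytest.approx(0.2)
        assert all(0.2 <= b <= 1.0 for b in b_seq)

    def test_bare_soil_cap_limits_growth_but_keeps_excess(self, arable_soil):
        cap_c = rothc.max_deficit(arable_soil, covered=True)
        cap_b = rothc.max_deficit(arable_soil, covered=False)
        state = MoistureState(acc_tsmd=0.0, max_tsmd=cap_c)
        for _ in range(24):
            _, state = rothc.rate_modifiers(20.0, 0.0, 80.0, False, state, arable_soil)
        assert state.acc_tsmd == pytest.approx(cap_b)
        # a deficit accumulated under cover persists under bare soil
        state = MoistureState(acc_tsmd=cap_c, max_tsmd=cap_c)
        _, state = rothc.rate_modifiers(20.0, 0.0, 80.0, False, state, arable_soil)
        assert state.acc_tsmd == pytest.approx(cap_c)

    def test_negative_precip_rejected(self, arable_soil):
        state = MoistureState(0.0, rothc.max_deficit(arable_soil))
        with pytest.raises(ValueError):
            rothc.rate_modifiers(10.0, -1.0, 40.0, True, state, arable_soil)


class TestPartition:
    def test_clay8(self, arable_soil):
        co2, bio, hum = rothc.partition_coefficients(arable_soil)
        x = 1.67 * (1.85 + 1.60 * np.exp(-0.0786 * 8.0))
        assert co2 == pytest.approx(x / (x + 1))
        assert co2 == pytest.approx(0.8187, abs=5e-4)

    def test_high_clay_limit(self):
        soil = SoilParams(clay=100.0)
        co2, _, _ = rothc.partition_coefficients(soil)
        limit = 3.0895 / 4.0895  # x -> 1.67*1.85 as clay -> inf
        assert co2 == pytest.approx(limit, abs=2e-3)

    @pytest.mark.parametrize("clay", [0.0, 8.0, 30.0, 60.0, 100.0])
    def test_fractions_sum_to_one(self, clay):
        co2, bio, hum = rothc.partition_coefficients(SoilParams(clay=clay))
        assert co2 + bio + hum == pytest.approx(1.0, abs=1e-14)
        assert bio / (bio + hum) == pytest.approx(0.46)


class TestIom:
    def test_values(self):
        assert rothc.iom_from_total(0.0) == 0.0
        assert rothc.iom_from_total(60.0) == pytest.approx(0.049 * 60.0**1.139)
        assert rothc.iom_from_total(80.0) > rothc.iom_from_total(60.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rothc.iom_from_total(-1.0)


class TestMonthlyStep:
    def test_no_input_no_decomposition(self, arable_soil):
        pools = PoolState(1.0, 2.0, 0.5, 10.0, 3.0)
        out, co2 = rothc.monthly_step(pools, 0.0, make_forcing(a=0.0), arable_soil)
        assert out.active == pytest.approx(pools.active)
        assert co2 == 0.0

    def test_single_pool_closed_form(self, arable_soil):
        pools = PoolState(1.0, 0.0, 0.0, 0.0, 0.0)
        out, _ = rothc.monthly_step(pools, 0.0, make_forcing(), arable_soil)
        assert out.dpm == pytest.approx(np.exp(-10.0 / 12.0))

    def test_iom_inert(self, arable_soil):
        pools = PoolState(1.0, 1.0, 1.0, 1.0, 7.7)
        out, _ = rothc.monthly_step(pools, 0.5, make_forcing(), arable_soil)
        assert out.iom == 7.7

    def test_negative_input_rejected(self, arable_soil):
        with pytest.raises(ValueError):
            rothc.monthly_step(PoolState(1, 1, 1, 1, 0), -0.1, make_forcing(), arable_soil)

    @settings(max_examples=200, deadline=None)
    @given(
        dpm=st.floats(0, 50), rpm=st.floats(0, 50), bio=st.floats(0, 20),
        hum=st.floats(0, 100), cin=st.floats(0, 2),
        a=st.floats(0, 10), b=st.floats(0.2, 1.0), clay=st.floats(0, 60),
    )
    def test_mass_balance_property(self, dpm, rpm, bio, hum, cin, a, b, clay):
        """Carbon input minus CO₂ efflux equals the active-pool change."""
        soil = SoilParams(clay=clay)
        pools = PoolState(dpm, rpm, bio, hum, 1.0)
        out, co2 = rothc.monthly_step(pools, cin, make_forcing(a=a, b=b), soil)
        delta = out.active.sum() - pools.active.sum()
        assert cin - co2 == pytest.approx(delta, abs=1e-10)
        assert np.all(out.active >= 0)


def constant_series(n, a=1.0, soil=None):
    return ForcingSeries(
        temp=np.full(n, 10.0), precip=np.full(n, 50.0), pet=np.full(n, 40.0),
        covered=np.ones(n, dtype=bool), a=np.full(n, a), b=np.ones(n),
        c=np.ones(n),
    )


class TestRunForward:
    def test_empty_sequence(self, arable_soil):
        p0 = PoolState(1, 1, 1, 1, 1)
        traj = rothc.run_forward(p0, constant_series(0), [], arable_soil)
        assert len(traj) == 1
        assert traj[0].active == pytest.approx(p0.active)

    def test_concatenation(self, arable_soil):
        rng = np.random.default_rng(0)
        p0 = PoolState(1.0, 2.0, 0.5, 10.0, 2.0)
        series = constant_series(24)
        inputs = rng.uniform(0, 0.3, 24)
        full = rothc.run_forward(p0, series, inputs, arable_soil)
        first = rothc.run_forward(
            p0, ForcingSeries(*[getattr(series, f)[:12] for f in
                                ("temp", "precip", "pet", "covered", "a", "b", "c")]),
            inputs[:12], arable_soil)
        second = rothc.run_forward(
            first[-1], ForcingSeries(*[getattr(series, f)[12:] for f in
                                       ("temp", "precip", "pet", "covered", "a", "b", "c")]),
            inputs[12:], arable_soil)
        assert second[-1].active == pytest.approx(full[-1].active, rel=1e-12)

    def test_affine_scaling(self, arable_soil):
        """Doubling active start pools and inputs doubles the active end pools."""
        series = constant_series(36)
        inputs = np.full(36, 0.2)
        p1 = PoolState(1.0, 2.0, 0.5, 10.0, 3.0)
        p2 = PoolState(2.0, 4.0, 1.0, 20.0, 3.0)
        t1 = rothc.run_forward(p1, series, inputs, arable_soil)
        t2 = rothc.run_forward(p2, series, 2 * inputs, arable_soil)
        assert t2[-1].active == pytest.approx(2 * t1[-1].active, rel=1e-12)

    def test_length_mismatch(self, arable_soil):
        with pytest.raises(ValueError):
            rothc.run_forward(PoolState(1, 1, 1, 1, 0), constant_series(5),
                              np.zeros(4), arable_soil)


class TestRunBackward:
    def test_zero_months(self, arable_soil):
        p = PoolState(1, 2, 3, 4, 5)
        traj, neg = rothc.run_backward(p, constant_series(0), [], arable_soil)
        assert len(traj) == 1 and not neg
        assert traj[0].active == pytest.approx(p.active)

    def test_constant_steady_state_stays_constant(self, arable_soil, temperate_cycle):
        from socbackcast import spinup

        iom = rothc.iom_from_total(60.0)
        pools = spinup.periodic_steady_pools(2.0, temperate_cycle, arable_soil, iom)
        n_years = 5
        series = ForcingSeries(*[np.tile(getattr(temperate_cycle, f), n_years) for f in
                                 ("temp", "precip", "pet", "covered", "a", "b", "c")])
        inputs = np.tile(np.full(12, 2.0 / 12.0), n_years)
        traj, neg = rothc.run_backward(pools, series, inputs, arable_soil)
        totals = np.array([t.total_soc for t in traj])
        assert not neg
        assert np.max(np.abs(totals[::12] - pools.total_soc)) < 1e-8

    def test_forward_oracle_roundtrip(self, arable_soil):
        """Backward reconstruction of a forward-attainable end state replays exactly."""
        rng = np.random.default_rng(3)
        n = 240
        series = ForcingSeries(
            temp=10 + 8 * rng.standard_normal(n), precip=np.abs(60 * rng.standard_normal(n)),
            pet=np.abs(40 * rng.standard_normal(n)), covered=np.ones(n, dtype=bool),
            a=np.clip(1 + 0.5 * rng.standard_normal(n), 0.05, None),
            b=rng.uniform(0.2, 1.0, n), c=np.where(rng.random(n) < 0.5, 0.6, 1.0),
        )
        inputs = rng.uniform(0, 0.4, n)
        start = np.array([0.3, 8.0, 1.0, 40.0])
        fwd, _ = rothc.forward_active(start, series, inputs, arable_soil)
        x_end = fwd[-1]
        back, _, _ = rothc.backward_active(x_end, series, inputs, arable_soil)
        replay, _ = rothc.forward_active(back[0], series, inputs, arable_soil)
        rel = np.abs(replay[-1] - x_end) / np.maximum(np.abs(x_end), 1e-12)
        assert rel.max() < 1e-6
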