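"""TEER, Ussing-chamber and impedance-trajectory readouts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barriereis import (
    CircuitParams,
    DeviceTrajectory,
    FrequencyGrid,
    TeerRecord,
    UssingTrace,
    endpoint_test,
    equilibrium_check,
    equilibrium_reached,
    qc_filter,
    simulate_spectrum,
    teer,
    teer_group_summary,
    ussing_resistance,
    zmag_at_100hz,
)
from barriereis.errors import DomainError, EquilibriumError, NoDeflectionError, PairingError
from barriereis.readouts import coculture_to_total_day, total_to_coculture_day
from barriereis.synth import gen_ussing_trace


def _rec(raw, blank, **kw):
    return TeerRecord(well_id="w", group="co-culture", day=14, raw_ohm=raw, blank_ohm=blank, **kw)


class TestTeer:
    @pytest.mark.parametrize(
        "raw, blank, expected, negative",
        [
            (100.0, 100.0, 0.0, False),
            (263.6, 100.0, 53.988, False),
            (90.0, 100.0, -3.3, True),
        ],
    )
    def test_formula_and_flag(self, raw, blank, expected, negative):
        v = teer(_rec(raw, blank))
        assert v.ohm_cm2 == pytest.approx(expected, abs=1e-9)
        assert v.negative is negative

    @settings(derandomize=True, max_examples=50)
    @given(
        raw=st.floats(0, 1e4), blank=st.floats(0, 1e4),
        shift=st.floats(0, 1e3),
    )
    def test_invariant_to_common_offset(self, raw, blank, shift):
        a = teer(_rec(raw, blank)).ohm_cm2
        b = teer(_rec(raw + shift, blank + shift)).ohm_cm2
        assert b == pytest.approx(a, abs=1e-6)

    def test_group_summary_hand_values(self):
        recs = [
            TeerRecord(f"w{v}", "g", 14, 100 + v / 0.33, 100.0)
            for v in (1.0, 2.0, 3.0)
        ]
        out = teer_group_summary(recs)
        assert out.loc[0, "mean"] == pytest.approx(2.0)
        assert out.loc[0, "sd"] == pytest.approx(1.0)
        assert out.loc[0, "n_wells"] == 3

    def test_identical_wells_sd_zero_and_singleton_sd_missing(self):
        two = [TeerRecord(f"w{i}", "g", 1, 150.0, 100.0) for i in range(2)]
        out = teer_group_summary(two)
        assert out.loc[0, "sd"] == 0.0
        single = teer_group_summary(two[:1])
        assert np.isnan(single.loc[0, "sd"])

    def test_readings_averaged_within_well(self):
        recs = [
            TeerRecord("w0", "g", 1, raw, 100.0, reading_index=k)
            for k, raw in enumerate((150.0, 160.0, 170.0))
        ]
        out = teer_group_summary(recs)
        assert out.loc[0, "n_wells"] == 1
        assert out.loc[0, "mean"] == pytest.approx(60.0 * 0.33)


def _flat_trace(minutes=35.0, level=2e-4):
    t = np.arange(0.0, minutes * 60.0)
    return UssingTrace(time_s=t, current_a=np.full_like(t, level))


class TestUssing:
    @pytest.mark.parametrize("r_tissue, delta_i", [(50.0, 1e-4), (1.0, 5e-3)])
    def test_ohms_law_inversion(self, r_tissue, delta_i):
        trace = gen_ussing_trace(r_tissue)
        r = ussing_resistance(trace)
        assert r.delta_i_a == pytest.approx(delta_i, rel=1e-12)
        assert r.ohm == pytest.approx(r_tissue, rel=1e-12)
        assert r.ohm_cm2 == pytest.approx(r_tissue * 0.33, rel=1e-12)

    def test_doubling_deflection_halves_resistance(self):
        r50 = ussing_resistance(gen_ussing_trace(50.0))
        r25 = ussing_resistance(gen_ussing_trace(25.0))
        assert r25.delta_i_a == pytest.approx(2 * r50.delta_i_a, rel=1e-12)
        assert r25.ohm == pytest.approx(r50.ohm / 2, rel=1e-12)

    def test_noisy_trace_recovered_within_3_percent(self):
        trace = gen_ussing_trace(50.0, noise_rel=0.01, seed=7)
        assert ussing_resistance(trace).ohm == pytest.approx(50.0, rel=0.03)

    def test_no_deflection_error(self):
        with pytest.raises(NoDeflectionError):
            ussing_resistance(_flat_trace(), clamp_start_s=32 * 60.0)

    def test_non_equilibrated_trace_rejected(self):
        t = np.arange(0.0, 35 * 60.0)
        i = 2e-4 * (1.0 + 0.1 * t / 60.0)  # 10%/min ramp
        i[t >= 32 * 60.0] += 1e-4
        with pytest.raises(EquilibriumError):
            ussing_resistance(UssingTrace(t, i), clamp_start_s=32 * 60.0)


class TestEquilibrium:
    def test_constant_trace_equilibrated(self):
        assert equilibrium_reached(_flat_trace(35.0)) is True

    def test_ramp_not_equilibrated(self):
        t = np.arange(0.0, 35 * 60.0)
        tr = UssingTrace(t, 2e-4 * (1.0 + 0.1 * t / 60.0))
        assert equilibrium_reached(tr) is False

    def test_short_trace_fails_with_reason(self):
        chk = equilibrium_check(_flat_trace(20.0))
        assert not chk and "s required" in chk.reason

    def test_noisy_flat_trace_equilibrated(self, rng):
        t = np.arange(0.0, 35 * 60.0)
        i = 2e-4 * (1.0 + 0.01 * rng.normal(size=t.size))
        assert equilibrium_reached(UssingTrace(t, i)) is True


class TestZmag100:
    def test_exact_grid_hit(self, example_params, example_spectrum):
        from barriereis import impedance

        assert zmag_at_100hz(example_spectrum) == pytest.approx(
            abs(impedance(example_params, 100.0)), rel=1e-13
        )

    def test_pure_resistor(self):
        p = CircuitParams(r1=100.0, rb=1e-9, cp=1e-12, q=1e6, alpha=0.5)
        sp = simulate_spectrum(p)
        assert zmag_at_100hz(sp) == pytest.approx(100.0, rel=1e-6)

    def test_off_grid_log_interpolation(self, example_params):
        # grid bracketing 100 Hz without containing it
        grid = FrequencyGrid(tuple(10.0 ** np.arange(4, -2.1, -0.5)))
        sp = simulate_spectrum(example_params, grid)
        got = zmag_at_100hz(sp)
        lo, hi = abs(sp.z[np.isclose(grid.as_array(), 10**2.5)][0]), abs(
            sp.z[np.isclose(grid.as_array(), 10**1.5)][0]
        )
        assert min(lo, hi) <= got <= max(lo, hi)

    def test_outside_span_rejected(self, example_params):
        sp = simulate_spectrum(example_params, FrequencyGrid((50.0, 25.0, 10.0, 5.0, 1.0, 0.5)))
        with pytest.raises(DomainError):
            zmag_at_100hz(sp)


def _traj(dev, z14):
    return DeviceTrajectory(dev, [0, 14], [80.0, z14], [15.0, 25.0], [60.0, 60.0])


class TestQcFilter:
    def test_inclusive_boundary(self):
        trajs = [_traj("a", 94.9), _traj("b", 95.0), _traj("c", 120.0)]
        kept, rejected = qc_filter(trajs)
        assert [t.device_id for t in kept] == ["b", "c"]
        assert rejected[0][0].device_id == "a" and "below" in rejected[0][1]

    def test_empty(self):
        assert qc_filter([]) == ([], [])

    def test_partition_and_idempotence(self):
        trajs = [_traj(f"d{i}", z) for i, z in enumerate((90, 95, 100, 80, 110))]
        kept, rejected = qc_filter(trajs)
        assert len(kept) + len(rejected) == len(trajs)
        kept2, rejected2 = qc_filter(kept)
        assert kept2 == kept and rejected2 == []

    def test_missing_day_rejected_with_reason(self):
        tr = DeviceTrajectory("x", [0, 10], [80.0, 90.0], [15.0, 20.0], [60.0, 60.0])
        kept, rejected = qc_filter([tr])
        assert kept == [] and "no measurement at day 14" in rejected[0][1]

    def test_known_pass_fraction(self):
        trajs = [_traj(f"p{i}", 100.0) for i in range(7)] + [
            _traj(f"f{i}", 90.0) for i in range(3)
        ]
        kept, rejected = qc_filter(trajs)
        assert len(kept) == 7 and len(rejected) == 3


class TestEndpointTest:
    def test_identical_arms(self):
        res = endpoint_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_unpaired_hand_formula(self):
        res = endpoint_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.kind == "unpaired"
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == 4

    def test_auto_pairs_on_matching_device_keys(self):
        a = {"d1": 1.0, "d2": 2.0, "d3": 3.0}
        b = {"d1": 2.0, "d2": 3.0, "d3": 5.0}
        assert endpoint_test(a, b).kind == "paired"
        del b["d3"]
        b["d4"] = 5.0
        assert endpoint_test(a, b).kind == "unpaired"

    def test_pairing_error_on_unequal_arms(self):
        with pytest.raises(PairingError):
            endpoint_test([1.0, 2.0, 3.0], [1.0, 2.0], paired=True)

    def test_day0_vs_day14_rb_power(self):
        """Cohorts at the reported day-0/day-14 Rb distributions (n = 10):
        significant at alpha = 0.05 in >= 95% of 100 seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            d0 = rng.normal(14.97, 3.36, 10)
            d14 = rng.normal(25.37, 3.30, 10)
            if endpoint_test(d0, d14).pvalue < 0.05:
                hits += 1
        assert hits >= 95


def test_day_clock_converters_roundtrip():
    assert coculture_to_total_day(0) == 6
    assert total_to_coculture_day(coculture_to_total_day(14)) == 14
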