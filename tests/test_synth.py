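"""Synthetic-data generators: calibration, determinism and recovery."""

import numpy as np
import pytest

from barriereis import (
    EisCohortSpec,
    SwitchCohortSpec,
    calibrate_defaults,
    endpoint_test,
    fit,
    fit_cohort,
    gen_eis_cohort,
    gen_switch_cohort,
    gen_teer_cohort,
    gen_ussing_trace,
    impedance,
    normalize,
    platform_summary,
    qc_filter,
    teer,
    teer_group_summary,
    zmag_at_100hz,
)
from barriereis.circuit import CircuitParams
from barriereis.errors import CalibrationError, DomainError
from barriereis.readouts import build_trajectories
from barriereis.synth import (
    RB_DAY0,
    RB_DAY14,
    ZMAG100_DAY0,
    ZMAG100_DAY14,
    growth_fraction,
)
from barriereis import simulate_spectrum


class TestCalibration:
    def test_zmag_constraints_hold(self):
        p0, p14 = calibrate_defaults()
        assert zmag_at_100hz(simulate_spectrum(p0)) == pytest.approx(ZMAG100_DAY0[0], abs=0.01)
        assert zmag_at_100hz(simulate_spectrum(p14)) == pytest.approx(ZMAG100_DAY14[0], abs=0.01)

    def test_rb_recovery_unperturbed_by_calibration(self):
        p0, p14 = calibrate_defaults()
        assert fit(simulate_spectrum(p0)).params.rb == pytest.approx(RB_DAY0[0], rel=1e-3)
        assert fit(simulate_spectrum(p14)).params.rb == pytest.approx(RB_DAY14[0], rel=1e-3)

    def test_root_verified_by_bisection_oracle(self):
        p0, _ = calibrate_defaults()

        def objective(lq):
            p = CircuitParams(p0.r1, p0.rb, p0.cp, 10.0**lq, p0.alpha)
            return abs(impedance(p, 100.0)) - ZMAG100_DAY0[0]

        lo, hi = -7.0, 1.0
        for _ in range(60):  # plain bisection to ~1e-17 interval
            mid = 0.5 * (lo + hi)
            if objective(lo) * objective(mid) <= 0:
                hi = mid
            else:
                lo = mid
        assert np.log10(p0.q) == pytest.approx(0.5 * (lo + hi), abs=1e-6)

    def test_unreachable_target_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_defaults(zmag_day0=1.0)  # below the resistive floor

    def test_q_decreases_as_barrier_matures(self):
        p0, p14 = calibrate_defaults()
        assert p14.q < p0.q  # scaffold infill absorbs the non-Rb |Z| surplus


class TestGrowthSchedule:
    def test_endpoints_and_split(self):
        assert growth_fraction(0) == 0.0
        assert growth_fraction(10) == pytest.approx(0.4)
        assert growth_fraction(14) == 1.0

    def test_late_slope_exceeds_early_slope(self):
        early = (growth_fraction(10) - growth_fraction(0)) / 10
        late = (growth_fraction(14) - growth_fraction(10)) / 4
        assert late > early


class TestEisCohort:
    def test_noiseless_mean_device_roundtrip(self):
        spec = EisCohortSpec(
            n_devices=1, days=(0, 14), rb_day0_sd=0.0, rb_day14_sd=0.0,
            r1_sd=0.0, noise_rel=0.0, seed=1,
        )
        spectra, truth = gen_eis_cohort(spec)
        fits = {sp.day: fit(sp) for sp in spectra}
        assert fits[0].params.rb == pytest.approx(RB_DAY0[0], rel=1e-3)
        assert fits[14].params.rb == pytest.approx(RB_DAY14[0], rel=1e-3)
        assert len(truth) == 2

    def test_deterministic_under_fixed_seed(self):
        spec = EisCohortSpec(n_devices=3, days=(0, 14), seed=9)
        s1, t1 = gen_eis_cohort(spec)
        s2, t2 = gen_eis_cohort(spec)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.z, b.z)
        assert t1.equals(t2)

    def test_truth_emitted_alongside(self):
        spec = EisCohortSpec(n_devices=2, days=(0, 2, 14), seed=4)
        spectra, truth = gen_eis_cohort(spec)
        assert len(spectra) == len(truth) == 6
        assert set(truth.columns) >= {"device_id", "day", "rb_ohm", "r1_ohm", "q_cpe"}

    def test_generated_rb_trajectory_property(self):
        spec = EisCohortSpec(n_devices=5, days=(0, 2, 4, 6, 8, 10, 12, 14), seed=2)
        _, truth = gen_eis_cohort(spec)
        for _, g in truth.groupby("device_id"):
            rb = g.sort_values("day")["rb_ohm"].to_numpy()
            assert np.all(np.diff(rb) >= -1e-12)
            days = g.sort_values("day")["day"].to_numpy()
            early = (rb[days == 10][0] - rb[days == 0][0]) / 10
            late = (rb[days == 14][0] - rb[days == 10][0]) / 4
            assert late > early or np.isclose(rb[-1], rb[0])

    def test_cohort_mean_day14_rb_within_2_sem(self):
        """Seeded default cohort (n = 10): fitted day-14 Rb mean within
        2 SEM of the reported 25.37 ohm."""
        spec = EisCohortSpec(n_devices=10, days=(0, 14), seed=20260930)
        spectra, _ = gen_eis_cohort(spec)
        day14 = [fit(sp).params.rb for sp in spectra if sp.day == 14]
        sem = RB_DAY14[1] / np.sqrt(len(day14))
        assert np.mean(day14) == pytest.approx(RB_DAY14[0], abs=2 * sem)

    def test_end_to_end_detects_barrier_growth(self):
        """generate -> fit -> qc -> endpoint test finds the day-0 vs day-14
        Rb difference in >= 95% of seeds (n = 10 devices, 100 seeds)."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            spec = EisCohortSpec(n_devices=10, days=(0, 14), seed=seed)
            spectra, _ = gen_eis_cohort(spec)
            fits = fit_cohort(spectra)
            trajs = build_trajectories(spectra, fits)
            kept, _ = qc_filter(trajs)
            d0 = {t.device_id: t.value_at_day(0, "rb") for t in kept}
            d14 = {t.device_id: t.value_at_day(14, "rb") for t in kept}
            if len(d0) >= 2 and endpoint_test(d0, d14).pvalue < 0.05:
                hits += 1
        assert hits >= int(0.95 * n_seeds)


class TestTeerCohort:
    def test_formula_inversion_roundtrip(self):
        records, truth = gen_teer_cohort(
            groups={"co-culture": (54.0, 0.0)}, n_wells=1, days=(14,), blank_sd=0.0, seed=0
        )
        assert teer(records[0]).ohm_cm2 == pytest.approx(54.0, rel=1e-12)
        assert truth.loc[0, "day14_teer_ohm_cm2"] == 54.0

    def test_deterministic_under_fixed_seed(self):
        a, _ = gen_teer_cohort(seed=5)
        b, _ = gen_teer_cohort(seed=5)
        assert a == b

    def test_logistic_rise_is_monotone(self):
        records, _ = gen_teer_cohort(
            groups={"co-culture": (54.0, 0.0)}, n_wells=1, blank_sd=0.0, seed=0
        )
        by_day = sorted({(r.day, teer(r).ohm_cm2) for r in records})
        values = [v for _, v in by_day]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_coculture_mean_within_2_sem(self):
        """Seeded co-culture cohort (n = 16 wells) recovers the reported
        54 ohm*cm^2 day-14 mean within 2 SEM."""
        records, _ = gen_teer_cohort(
            groups={"co-culture": (54.0, 6.0)}, n_wells=16, days=(14,), seed=20260930
        )
        out = teer_group_summary(records)
        sem = 6.0 / np.sqrt(16)
        assert out.loc[0, "mean"] == pytest.approx(54.0, abs=2 * sem)


class TestUssingGenerator:
    def test_rejects_nonpositive_resistance(self):
        with pytest.raises(DomainError):
            gen_ussing_trace(0.0)

    def test_pulse_height_is_ohms_law(self):
        trace = gen_ussing_trace(1.0)
        assert trace.current_a.max() - trace.current_a.min() == pytest.approx(5e-3, rel=1e-12)

    def test_deterministic_under_fixed_seed(self):
        a = gen_ussing_trace(50.0, noise_rel=0.01, seed=11)
        b = gen_ussing_trace(50.0, noise_rel=0.01, seed=11)
        np.testing.assert_array_equal(a.current_a, b.current_a)


class TestSwitchCohort:
    def test_null_effects_normalize_to_ones(self):
        spec = SwitchCohortSpec(
            platform="2D", n=5, baseline_mean=54.0, baseline_sd=6.0,
            egta_effect_mean=1.0, egta_effect_sd=0.0,
            washout_effect_mean=1.0, washout_effect_sd=0.0, seed=0,
        )
        series, _ = gen_switch_cohort(spec)
        for s in series:
            n = normalize(s)
            assert n.egta == pytest.approx(1.0) and n.washout == pytest.approx(1.0)

    def test_deterministic_under_fixed_seed(self):
        spec = SwitchCohortSpec.for_platform("3D", seed=8)
        a, ta = gen_switch_cohort(spec)
        b, tb = gen_switch_cohort(spec)
        assert a == b and ta.equals(tb)

    def test_unknown_platform_rejected(self):
        with pytest.raises(DomainError):
            SwitchCohortSpec.for_platform("4D")

    def test_2d_egta_mean_within_2_sem(self):
        """Seeded 2D cohort (n = 11) recovers the reported EGTA-phase
        normalized mean of 0.83 within 2 SEM."""
        spec = SwitchCohortSpec.for_platform("2D", seed=20260930)
        series, _ = gen_switch_cohort(spec)
        out = platform_summary([normalize(s) for s in series])
        egta = out[out["phase"] == "egta"].iloc[0]
        sem = 0.09 / np.sqrt(11)
        assert egta["mean"] == pytest.approx(0.83, abs=2 * sem)

    def test_replicate_counts_match_study(self):
        for platform, n in (("2D", 11), ("3D", 9), ("ex-vivo", 9)):
            series, _ = gen_switch_cohort(SwitchCohortSpec.for_platform(platform, seed=0))
            assert len(series) == n
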