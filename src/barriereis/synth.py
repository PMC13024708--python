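"""Synthetic-data generators for the three barrier-measurement platforms.

Every generator is a pure function of its spec and seed, and emits its
ground truth alongside the data, so downstream recovery error is always
measurable.  Defaults encode the study conditions the analysis targets:

* EIS cohorts: day-0 and day-14 barrier resistance Rb of 14.97 +/- 3.36
  and 25.37 +/- 3.30 ohm on the co-culture clock, measured every 2 days
  on the 61-point default sweep, with nuisance parameters calibrated so
  the noiseless mean device also reproduces the reported |Z|(100 Hz)
  endpoints of 82.08 and 107.26 ohm.  The |Z| increase exceeds the Rb
  increase; the surplus is attributed to the scaffold CPE (Q falling as
  cells infill the pores), which keeps R1 constant, as observed.
* Barrier growth: Rb(t) rises piecewise-linearly with 40% of the total
  increase over days 0-10 and 60% over days 10-14, reflecting the
  accelerated growth after confluence.
* TEER tables: day-14 group targets of 54 +/- 6 (co-culture),
  27 +/- 8 (IEC-6) and 20 +/- 3 (208F) ohm*cm^2 approached along a
  logistic rise, emitted as raw/blank voltohmmeter pairs (blank
  100 +/- 5 ohm nominal).
* Ussing traces: a 5 mV clamp producing dI = V / R_tissue square pulses
  on a >= 35 min baseline.
* Calcium-switch tables: per-replicate baseline draws times
  multiplicative EGTA/washout effects, platform defaults set to the
  reported normalized means/SDs with n = 11 / 9 / 9 (2D / 3D / ex vivo).

Noise is i.i.d. complex Gaussian with per-point standard deviation
``noise_rel * |Z|`` on each quadrature component (EIS), or proportional
Gaussian on scalar signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .circuit import CircuitParams, FrequencyGrid, ImpedanceSpectrum, impedance, simulate_spectrum
from .errors import CalibrationError, DomainError
from .readouts import INSERT_AREA_CM2, TeerRecord, UssingTrace
from .switchstats import CalciumSwitchSeries

__all__ = [
    "RB_DAY0", "RB_DAY14", "ZMAG100_DAY0", "ZMAG100_DAY14",
    "TEER_GROUP_DEFAULTS", "SWITCH_PLATFORM_DEFAULTS",
    "EisCohortSpec", "SwitchCohortSpec",
    "calibrate_defaults", "gen_eis_cohort", "gen_teer_cohort",
    "gen_ussing_trace", "gen_switch_cohort", "growth_fraction",
]

# Reported co-culture endpoints (mean, SD), co-culture clock.
RB_DAY0 = (14.97, 3.36)      # ohm
RB_DAY14 = (25.37, 3.30)     # ohm
ZMAG100_DAY0 = (82.08, 12.00)   # ohm
ZMAG100_DAY14 = (107.26, 8.04)  # ohm

# Day-14 TEER targets per 2D group (mean, SD), ohm*cm^2.
TEER_GROUP_DEFAULTS = {
    "co-culture": (54.0, 6.0),
    "monoculture-IEC6": (27.0, 8.0),
    "monoculture-208F": (20.0, 3.0),
}

# Calcium-switch platform defaults: replicate count, baseline (platform-native
# units) and multiplicative EGTA/washout effects (normalized mean, SD).
SWITCH_PLATFORM_DEFAULTS = {
    "2D": dict(n=11, baseline=(54.0, 6.0), egta=(0.83, 0.09), washout=(0.68, 0.13)),
    "3D": dict(n=9, baseline=(25.37, 3.30), egta=(0.99, 0.13), washout=(0.83, 0.03)),
    "ex-vivo": dict(n=9, baseline=(90.0, 15.0), egta=(0.85, 0.16), washout=(0.54, 0.14)),
}

# Fixed nuisance values held during calibration.
NUISANCE_R1 = 60.0       # ohm
NUISANCE_CP = 5e-6       # F
NUISANCE_ALPHA = 0.85

#: Fraction of the day-0 -> day-14 Rb increase accrued by day 10.
GROWTH_SPLIT_DAY = 10
GROWTH_SPLIT_FRACTION = 0.4


def growth_fraction(day: float) -> float:
    """Piecewise-linear barrier growth schedule s(t): s(0)=0, s(10)=0.4, s(14)=1."""
    if day <= 0:
        return 0.0
    if day <= GROWTH_SPLIT_DAY:
        return GROWTH_SPLIT_FRACTION * day / GROWTH_SPLIT_DAY
    if day >= 14:
        return 1.0
    return GROWTH_SPLIT_FRACTION + (1.0 - GROWTH_SPLIT_FRACTION) * (day - GROWTH_SPLIT_DAY) / (14 - GROWTH_SPLIT_DAY)


def calibrate_defaults(
    r1: float = NUISANCE_R1,
    cp: float = NUISANCE_CP,
    alpha: float = NUISANCE_ALPHA,
    rb_day0: float = RB_DAY0[0],
    rb_day14: float = RB_DAY14[0],
    zmag_day0: float = ZMAG100_DAY0[0],
    zmag_day14: float = ZMAG100_DAY14[0],
) -> tuple:
    """Solve the CPE magnitude Q per endpoint so both constraints hold.

    Holding r1, cp and alpha fixed and rb at its day mean, a 1-D root
    find on log10(Q) makes the noiseless mean device satisfy the
    |Z|(100 Hz) endpoint for each of day 0 and day 14.  |Z|(100 Hz) is
    strictly decreasing in Q, so the root is unique when bracketed.

    Returns ``(params_day0, params_day14)``.
    """
    out = []
    for rb, target in ((rb_day0, zmag_day0), (rb_day14, zmag_day14)):
        def objective(lq: float) -> float:
            p = CircuitParams(r1=r1, rb=rb, cp=cp, q=10.0 ** lq, alpha=alpha)
            return abs(impedance(p, 100.0)) - target

        lo, hi = -7.0, 1.0
        if objective(lo) * objective(hi) > 0:
            raise CalibrationError(
                f"|Z|(100 Hz) target {target} ohm not bracketed by Q in "
                f"[1e-7, 10] with rb = {rb} ohm"
            )
        lq = brentq(objective, lo, hi, xtol=1e-13)
        out.append(CircuitParams(r1=r1, rb=rb, cp=cp, q=10.0 ** lq, alpha=alpha))
    return tuple(out)


@dataclass(frozen=True)
class EisCohortSpec:
    """Study conditions for a synthetic EIS cohort."""

    n_devices: int = 10
    days: tuple = (0, 2, 4, 6, 8, 10, 12, 14)
    rb_day0_mean: float = RB_DAY0[0]
    rb_day0_sd: float = RB_DAY0[1]
    rb_day14_mean: float = RB_DAY14[0]
    rb_day14_sd: float = RB_DAY14[1]
    r1_mean: float = NUISANCE_R1
    r1_sd: float = 5.0
    endpoint_corr: float = 0.5
    noise_rel: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_devices < 1:
            raise DomainError("n_devices must be >= 1")
        if min(self.rb_day0_mean, self.rb_day14_mean, self.r1_mean) <= 0:
            raise DomainError("means must be > 0")
        if min(self.rb_day0_sd, self.rb_day14_sd, self.r1_sd, self.noise_rel) < 0:
            raise DomainError("sds and noise_rel must be >= 0")
        if not -1.0 <= self.endpoint_corr <= 1.0:
            raise DomainError("endpoint_corr must be in [-1, 1]")


def gen_eis_cohort(spec: EisCohortSpec, grid: FrequencyGrid | None = None):
    """Generate per-device, per-day spectra plus the ground-truth table.

    Per device, the (day 0, day 14) Rb endpoints are drawn from a
    bivariate normal with the spec means/SDs and ``endpoint_corr``
    (truncated at 0.1 ohm); Rb(t) follows :func:`growth_fraction`.  R1 is
    constant per device.  log10(Q) is interpolated between the calibrated
    day-0/day-14 values along the same schedule; cp and alpha are fixed.

    Returns ``(spectra, truth)`` where ``truth`` is a DataFrame with one
    row per device/day carrying the generating parameters.
    """
    if grid is None:
        grid = FrequencyGrid.default()
    rng = np.random.default_rng(spec.seed)
    p0, p14 = calibrate_defaults(
        r1=spec.r1_mean, rb_day0=spec.rb_day0_mean, rb_day14=spec.rb_day14_mean
    )
    lq0, lq14 = math.log10(p0.q), math.log10(p14.q)
    cov = np.array(
        [
            [spec.rb_day0_sd ** 2, spec.endpoint_corr * spec.rb_day0_sd * spec.rb_day14_sd],
            [spec.endpoint_corr * spec.rb_day0_sd * spec.rb_day14_sd, spec.rb_day14_sd ** 2],
        ]
    )
    mean = np.array([spec.rb_day0_mean, spec.rb_day14_mean])
    spectra, rows = [], []
    for i in range(spec.n_devices):
        dev = f"dev{i:02d}"
        rb0, rb14 = np.clip(rng.multivariate_normal(mean, cov), 0.1, None)
        r1 = max(float(rng.normal(spec.r1_mean, spec.r1_sd)), 0.5)
        for day in spec.days:
            s = growth_fraction(day)
            rb = float(rb0 + (rb14 - rb0) * s)
            q = 10.0 ** (lq0 + (lq14 - lq0) * s)
            params = CircuitParams(r1=r1, rb=rb, cp=p0.cp, q=q, alpha=p0.alpha)
            sp = simulate_spectrum(params, grid, device_id=dev, day=day)
            if spec.noise_rel > 0:
                scale = spec.noise_rel * np.abs(sp.z)
                sp.z = sp.z + scale * rng.normal(size=len(sp)) + 1j * scale * rng.normal(size=len(sp))
            spectra.append(sp)
            rows.append(
                {"device_id": dev, "day": day, "r1_ohm": r1, "rb_ohm": rb,
                 "cp_farad": p0.cp, "q_cpe": q, "alpha": p0.alpha}
            )
    return spectra, pd.DataFrame(rows)


def gen_teer_cohort(
    groups: dict | None = None,
    n_wells: int = 8,
    days: tuple = tuple(range(1, 15)),
    blank_mean: float = 100.0,
    blank_sd: float = 5.0,
    reading_noise_ohm: float = 0.0,
    n_readings: int = 3,
    area_cm2: float = INSERT_AREA_CM2,
    seed: int = 0,
):
    """Generate voltohmmeter TEER tables with a logistic 14-day rise.

    Per well, a day-14 TEER target is drawn from the group distribution
    and approached along a logistic curve (midpoint day 7, scale 2 days,
    rescaled so the day-14 value hits the target exactly).  Records
    invert the TEER formula: ``raw = blank + teer / area``.

    Returns ``(records, truth)`` where ``truth`` has one row per well
    with its day-14 target.
    """
    if groups is None:
        groups = dict(TEER_GROUP_DEFAULTS)
    rng = np.random.default_rng(seed)
    logistic = lambda t: 1.0 / (1.0 + math.exp(-(t - 7.0) / 2.0))
    norm = logistic(14.0)
    records, rows = [], []
    for group, (mean, sd) in groups.items():
        for w in range(n_wells):
            well = f"{group}-w{w:02d}"
            target = float(rng.normal(mean, sd)) if sd > 0 else mean
            blank = float(rng.normal(blank_mean, blank_sd)) if blank_sd > 0 else blank_mean
            blank = max(blank, 1.0)
            rows.append({"well_id": well, "group": group, "day14_teer_ohm_cm2": target})
            for day in days:
                value = target * logistic(day) / norm
                raw = blank + value / area_cm2
                for k in range(n_readings):
                    noise = float(rng.normal(0.0, reading_noise_ohm)) if reading_noise_ohm > 0 else 0.0
                    records.append(
                        TeerRecord(
                            well_id=well, group=group, day=day,
                            raw_ohm=max(raw + noise, 0.0), blank_ohm=blank,
                            area_cm2=area_cm2, reading_index=k,
                        )
                    )
    return records, pd.DataFrame(rows)


def gen_ussing_trace(
    r_tissue: float,
    noise_rel: float = 0.0,
    seed: int | None = None,
    clamp_voltage_v: float = 5e-3,
    area_cm2: float = INSERT_AREA_CM2,
    baseline_a: float = 2e-4,
    duration_s: float = 2160.0,
    sample_hz: float = 1.0,
    clamp_start_s: float = 1920.0,
    pulse_on_s: float = 60.0,
    pulse_off_s: float = 60.0,
    n_pulses: int = 2,
) -> UssingTrace:
    """Generate a clamped-voltage current trace with square pulses.

    The baseline runs for >= 30 min before the first pulse; each pulse
    adds ``dI = V / r_tissue``.  Proportional Gaussian noise
    (``noise_rel`` of the local current) is applied when requested.
    """
    if r_tissue <= 0:
        raise DomainError("r_tissue must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, 1.0 / sample_hz)
    i = np.full_like(t, baseline_a)
    delta_i = clamp_voltage_v / r_tissue
    for k in range(n_pulses):
        start = clamp_start_s + k * (pulse_on_s + pulse_off_s)
        i[(t >= start) & (t < start + pulse_on_s)] += delta_i
    if noise_rel > 0:
        i = i * (1.0 + noise_rel * rng.normal(size=t.size))
    return UssingTrace(time_s=t, current_a=i, clamp_voltage_v=clamp_voltage_v, area_cm2=area_cm2)


@dataclass(frozen=True)
class SwitchCohortSpec:
    """Study conditions for one platform of the calcium-switch assay."""

    platform: str
    n: int
    baseline_mean: float
    baseline_sd: float
    egta_effect_mean: float
    egta_effect_sd: float
    washout_effect_mean: float
    washout_effect_sd: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DomainError("n must be >= 2")
        if self.baseline_mean <= 0 or self.egta_effect_mean <= 0 or self.washout_effect_mean <= 0:
            raise DomainError("means and effects must be > 0")
        if min(self.baseline_sd, self.egta_effect_sd, self.washout_effect_sd) < 0:
            raise DomainError("sds must be >= 0")

    @classmethod
    def for_platform(cls, platform: str, seed: int = 0, n: int | None = None) -> "SwitchCohortSpec":
        """Spec preloaded with the study defaults for ``platform``."""
        try:
            d = SWITCH_PLATFORM_DEFAULTS[platform]
        except KeyError:
            raise DomainError(
                f"unknown platform {platform!r}; expected one of "
                f"{sorted(SWITCH_PLATFORM_DEFAULTS)}"
            ) from None
        return cls(
            platform=platform, n=d["n"] if n is None else n,
            baseline_mean=d["baseline"][0], baseline_sd=d["baseline"][1],
            egta_effect_mean=d["egta"][0], egta_effect_sd=d["egta"][1],
            washout_effect_mean=d["washout"][0], washout_effect_sd=d["washout"][1],
            seed=seed,
        )


def gen_switch_cohort(spec: SwitchCohortSpec):
    """Generate a calcium-switch table for one platform.

    Baselines are drawn per replicate; EGTA and washout values multiply
    the replicate's own baseline by independent effect draws (truncated
    at 0.01), so the normalized values recover the effect distributions
    exactly.  Returns ``(series, truth)``.
    """
    rng = np.random.default_rng(spec.seed)
    series, rows = [], []
    for i in range(spec.n):
        rid = f"{spec.platform}-r{i:02d}"
        baseline = max(float(rng.normal(spec.baseline_mean, spec.baseline_sd)), 0.01)
        egta_eff = max(float(rng.normal(spec.egta_effect_mean, spec.egta_effect_sd)), 0.01)
        wash_eff = max(float(rng.normal(spec.washout_effect_mean, spec.washout_effect_sd)), 0.01)
        series.append(
            CalciumSwitchSeries(
                replicate_id=rid, platform=spec.platform,
                baseline=baseline, egta=baseline * egta_eff, washout=baseline * wash_eff,
            )
        )
        rows.append(
            {"replicate_id": rid, "platform": spec.platform, "baseline": baseline,
             "egta_effect": egta_eff, "washout_effect": wash_eff}
        )
    return series, pd.DataFrame(rows)
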