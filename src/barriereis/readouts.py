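"""Platform-specific barrier-resistance readouts.

Three measurement modalities are covered:

* **TEER** (2D inserts, voltohmmeter): ``TEER [ohm*cm^2] =
  (raw - blank) * area`` with the 24-well insert growth area 0.33 cm^2.
* **Ussing chamber** (ex vivo): a 5 mV clamp applied to the tissue; the
  resistance follows Ohm's law ``R = V / dI`` where ``dI`` is the current
  deflection attributable to the clamp step.
* **EIS trajectory** (3D device): |Z| extracted at 100 Hz per day, the
  fitted barrier resistance Rb per day, and the day-14 quality-control
  rule (|Z|(100 Hz) >= 95 ohm) that gates device inclusion.

Days run on the co-culture clock: day 0 = epithelial seeding, which for
the 3D device is total-culture day 6 (``coculture_to_total_day``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .circuit import ImpedanceSpectrum, interp_zmag
from .errors import DomainError, EquilibriumError, NoDeflectionError, PairingError

__all__ = [
    "TeerRecord",
    "TeerValue",
    "UssingTrace",
    "UssingResistance",
    "DeviceTrajectory",
    "EquilibriumCheck",
    "EndpointTest",
    "teer",
    "teer_group_summary",
    "ussing_resistance",
    "equilibrium_reached",
    "equilibrium_check",
    "zmag_at_100hz",
    "qc_filter",
    "endpoint_test",
    "build_trajectories",
    "coculture_to_total_day",
    "total_to_coculture_day",
    "QC_THRESHOLD_OHM",
    "QC_DAY",
    "INSERT_AREA_CM2",
]

#: Growth area of a 24-well insert / Ussing aperture, cm^2.
INSERT_AREA_CM2 = 0.33
#: Inclusion rule for 3D devices: |Z|(100 Hz) at day 14 must reach this.
QC_THRESHOLD_OHM = 95.0
QC_DAY = 14
#: Offset between the co-culture clock and total culture days (3D device).
COCULTURE_DAY_OFFSET = 6


def coculture_to_total_day(day: int) -> int:
    return day + COCULTURE_DAY_OFFSET


def total_to_coculture_day(day: int) -> int:
    return day - COCULTURE_DAY_OFFSET


@dataclass(frozen=True)
class TeerRecord:
    """One voltohmmeter reading of a 2D insert well."""

    well_id: str
    group: str
    day: int
    raw_ohm: float
    blank_ohm: float
    area_cm2: float = INSERT_AREA_CM2
    reading_index: int = 0

    def __post_init__(self) -> None:
        if self.raw_ohm < 0 or self.blank_ohm < 0:
            raise DomainError("raw and blank resistances must be >= 0")
        if self.area_cm2 <= 0:
            raise DomainError("area must be > 0")


class TeerValue(NamedTuple):
    """Area-normalized TEER with a flag for blank-exceeds-raw readings."""

    ohm_cm2: float
    negative: bool

    def __float__(self) -> float:
        return self.ohm_cm2


def teer(record: TeerRecord) -> TeerValue:
    """``(raw - blank) * area`` in ohm*cm^2.

    Negative values (blank exceeding raw, a measurement problem) are
    returned flagged, not discarded: exclusion is the caller's policy.
    """
    v = (record.raw_ohm - record.blank_ohm) * record.area_cm2
    return TeerValue(ohm_cm2=v, negative=v < 0)


def teer_group_summary(records) -> pd.DataFrame:
    """Per-group, per-day mean and sample SD of well-level TEER.

    Readings within a well are blank-subtracted then averaged (identical
    to average-then-subtract for a shared blank); the summary statistics
    are then taken across wells.  Groups/days with a single well report a
    missing SD rather than raising.
    """
    rows = [
        {
            "group": r.group,
            "day": r.day,
            "well_id": r.well_id,
            "teer": teer(r).ohm_cm2,
        }
        for r in records
    ]
    if not rows:
        return pd.DataFrame(columns=["group", "day", "mean", "sd", "n_wells"])
    df = pd.DataFrame(rows)
    wells = df.groupby(["group", "day", "well_id"], as_index=False)["teer"].mean()
    out = (
        wells.groupby(["group", "day"])["teer"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n_wells="count")
        .reset_index()
    )
    return out


@dataclass
class UssingTrace:
    """A clamped-voltage current--time trace from an Ussing chamber."""

    time_s: np.ndarray
    current_a: np.ndarray
    clamp_voltage_v: float = 5e-3
    area_cm2: float = INSERT_AREA_CM2

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        i = np.asarray(self.current_a, dtype=float)
        if t.ndim != 1 or t.shape != i.shape:
            raise DomainError("time and current must be 1-D and equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise DomainError("time must be strictly increasing")
        if self.clamp_voltage_v <= 0:
            raise DomainError("clamp voltage must be > 0")
        self.time_s = t
        self.current_a = i

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass(frozen=True)
class EquilibriumCheck:
    """Truthy iff the baseline is equilibrated; carries the reason if not."""

    equilibrated: bool
    drift_per_min: float
    reason: str = ""

    def __bool__(self) -> bool:
        return self.equilibrated


def equilibrium_check(
    trace: UssingTrace,
    min_duration_s: float = 1800.0,
    window_s: float = 600.0,
    max_drift_frac_per_min: float = 0.01,
) -> EquilibriumCheck:
    """Operational equilibrium criterion for the pre-clamp baseline.

    The trace must cover at least 30 min, and the linear drift of the
    final 10-minute window must stay below 1% of its mean current per
    minute.
    """
    if trace.duration_s < min_duration_s:
        return EquilibriumCheck(
            False, float("nan"),
            f"trace covers {trace.duration_s:.0f} s; >= {min_duration_s:.0f} s required",
        )
    t0 = trace.time_s[-1] - window_s
    m = trace.time_s >= t0
    t, i = trace.time_s[m], trace.current_a[m]
    slope = np.polyfit(t, i, 1)[0]  # A/s
    drift_per_min = abs(slope) * 60.0
    mean_abs = max(abs(float(np.mean(i))), 1e-15)
    ok = bool(drift_per_min < max_drift_frac_per_min * mean_abs)
    return EquilibriumCheck(
        ok, drift_per_min,
        "" if ok else f"baseline drift {drift_per_min:.3g} A/min exceeds "
        f"{max_drift_frac_per_min:.0%}/min of mean {mean_abs:.3g} A",
    )


def equilibrium_reached(trace: UssingTrace, **kwargs) -> bool:
    """Boolean view of :func:`equilibrium_check`."""
    return bool(equilibrium_check(trace, **kwargs))


@dataclass(frozen=True)
class UssingResistance:
    """Ohm's-law resistance from a clamp step, raw and area-normalized."""

    ohm: float
    ohm_cm2: float
    delta_i_a: float
    clamp_start_s: float


def ussing_resistance(
    trace: UssingTrace,
    clamp_start_s: float | None = None,
    window_s: float = 60.0,
    require_equilibrium: bool = True,
) -> UssingResistance:
    """Tissue resistance ``R = V / dI`` from a clamped-voltage trace.

    ``dI`` is the mean current during the clamp window minus the mean of
    the baseline window immediately preceding it (both ``window_s`` long,
    default 60 s).  When ``clamp_start_s`` is not given, the clamp onset
    is located at the largest positive sample-to-sample current jump.

    Raises :class:`EquilibriumError` if the pre-clamp baseline has not
    equilibrated, and :class:`NoDeflectionError` when ``dI`` is
    non-positive or below 3x the baseline noise.
    """
    t, i = trace.time_s, trace.current_a
    if clamp_start_s is None:
        if len(i) < 3:
            raise NoDeflectionError("trace too short to locate a clamp step")
        # first rise comparable to the largest jump (robust to repeated pulses)
        d = np.diff(i)
        idx = int(np.argmax(d >= 0.5 * d.max())) if d.max() > 0 else int(np.argmax(d))
        clamp_start_s = float(t[idx + 1])
    if require_equilibrium:
        pre = t < clamp_start_s
        if pre.sum() < 2:
            raise EquilibriumError("no pre-clamp baseline in trace")
        chk = equilibrium_check(UssingTrace(t[pre], i[pre], trace.clamp_voltage_v, trace.area_cm2))
        if not chk:
            raise EquilibriumError(chk.reason)
    base = (t >= clamp_start_s - window_s) & (t < clamp_start_s)
    clamp = (t >= clamp_start_s) & (t < clamp_start_s + window_s)
    if base.sum() == 0 or clamp.sum() == 0:
        raise NoDeflectionError("analysis windows contain no samples")
    i_base = float(np.mean(i[base]))
    i_clamp = float(np.mean(i[clamp]))
    delta_i = i_clamp - i_base
    noise = float(np.std(i[base]))
    if delta_i <= 0 or delta_i < 3.0 * noise:
        raise NoDeflectionError(
            f"current deflection {delta_i:.3g} A is non-positive or below the "
            f"noise floor (3 sd = {3 * noise:.3g} A)"
        )
    r = trace.clamp_voltage_v / delta_i
    return UssingResistance(
        ohm=r, ohm_cm2=r * trace.area_cm2, delta_i_a=delta_i, clamp_start_s=clamp_start_s
    )


def zmag_at_100hz(spectrum: ImpedanceSpectrum) -> float:
    """|Z| extracted at 100 Hz (exact grid hit or log-linear interpolation)."""
    return interp_zmag(spectrum, 100.0)


@dataclass
class DeviceTrajectory:
    """Per-device time series of |Z|(100 Hz), Rb and R1 on the co-culture clock."""

    device_id: str
    days: list
    zmag_100hz: list
    rb: list
    r1: list
    qc_pass: bool | None = None

    def __post_init__(self) -> None:
        n = len(self.days)
        if not (len(self.zmag_100hz) == n and len(self.rb) == n and len(self.r1) == n):
            raise DomainError("trajectory columns must share one length")
        if n > 1 and not all(b > a for a, b in zip(self.days, self.days[1:])):
            raise DomainError("days must be strictly increasing")

    def value_at_day(self, day: int, column: str = "zmag_100hz"):
        try:
            idx = self.days.index(day)
        except ValueError:
            return None
        return getattr(self, column)[idx]


def build_trajectories(spectra, fits) -> list:
    """Assemble :class:`DeviceTrajectory` objects from spectra and their fits.

    ``fits`` is the output of :func:`barriereis.fitting.fit_cohort` aligned
    with ``spectra``; days with a :class:`FitFailure` contribute the |Z|
    sample with missing rb/r1.
    """
    per_device: dict = {}
    for sp, fr in zip(spectra, fits):
        rec = per_device.setdefault(sp.device_id, {})
        rb = getattr(fr, "params", None)
        rec[sp.day] = (
            zmag_at_100hz(sp),
            rb.rb if rb is not None else float("nan"),
            rb.r1 if rb is not None else float("nan"),
        )
    out = []
    for dev, by_day in per_device.items():
        days = sorted(by_day)
        out.append(
            DeviceTrajectory(
                device_id=dev,
                days=days,
                zmag_100hz=[by_day[d][0] for d in days],
                rb=[by_day[d][1] for d in days],
                r1=[by_day[d][2] for d in days],
            )
        )
    return out


def qc_filter(
    trajectories,
    threshold: float = QC_THRESHOLD_OHM,
    at_day: int = QC_DAY,
):
    """Partition trajectories by the day-14 |Z|(100 Hz) inclusion rule.

    Returns ``(kept, rejected)`` where ``rejected`` items are
    ``(trajectory, reason)`` pairs.  The boundary is inclusive (>=).
    Devices missing the ``at_day`` measurement are rejected with a reason.
    ``qc_pass`` is stamped on every trajectory.
    """
    kept, rejected = [], []
    for tr in trajectories:
        z = tr.value_at_day(at_day, "zmag_100hz")
        if z is None:
            tr.qc_pass = False
            rejected.append((tr, f"no measurement at day {at_day}"))
        elif z >= threshold:
            tr.qc_pass = True
            kept.append(tr)
        else:
            tr.qc_pass = False
            rejected.append(
                (tr, f"|Z|(100 Hz) = {z:.2f} ohm at day {at_day} below {threshold} ohm")
            )
    return kept, rejected


@dataclass(frozen=True)
class EndpointTest:
    """A two-tailed t-test between two endpoint arms."""

    statistic: float
    pvalue: float
    df: float
    kind: str  # "paired" | "unpaired" | "welch"


def endpoint_test(values_day0, values_day14, paired: str | bool = "auto",
                  equal_var: bool = True) -> EndpointTest:
    """Two-tailed Student's t-test of day-0 vs day-14 values.

    Arms may be sequences or device-keyed mappings.  With ``paired="auto"``
    a paired test is used when both arms are mappings over the same device
    keys; otherwise the unpaired equal-variance Student test (the paper's
    fallback when technical failures break pairing).  ``equal_var=False``
    selects Welch's test for the unpaired branch.
    """
    keyed = isinstance(values_day0, dict) and isinstance(values_day14, dict)
    if paired == "auto":
        use_paired = keyed and set(values_day0) == set(values_day14)
    else:
        use_paired = bool(paired)
    if keyed:
        if use_paired:
            keys = sorted(set(values_day0) & set(values_day14))
            if set(values_day0) != set(values_day14):
                raise PairingError("paired test requested on incomplete device pairs")
            a = np.array([values_day0[k] for k in keys], dtype=float)
            b = np.array([values_day14[k] for k in keys], dtype=float)
        else:
            a = np.array(list(values_day0.values()), dtype=float)
            b = np.array(list(values_day14.values()), dtype=float)
    else:
        a = np.asarray(list(values_day0), dtype=float)
        b = np.asarray(list(values_day14), dtype=float)
        if use_paired and a.size != b.size:
            raise PairingError(
                f"paired test requested with unequal arms ({a.size} vs {b.size})"
            )
    if a.size < 2 or b.size < 2:
        raise DomainError("each arm needs >= 2 values")
    if use_paired:
        res = stats.ttest_rel(a, b)
        df = float(a.size - 1)
        kind = "paired"
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        df = float(res.df) if hasattr(res, "df") else float(a.size + b.size - 2)
        kind = "unpaired" if equal_var else "welch"
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # identical constant arms: no variance anywhere
        t, p = 0.0, 1.0
    return EndpointTest(statistic=t, pvalue=p, df=df, kind=kind)
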