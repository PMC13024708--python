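"""Readers and writers for the package's delimited-text dialects.

All files are comma-separated UTF-8 with a mandatory header row and '.'
decimal separator.  Numeric output is written at full double precision
(17 significant digits), so every writer/reader pair is a lossless round
trip.  Errors name the offending 1-based file line.

Dialects
--------
* Spectra: ``device_id, day, frequency_hz, z_real_ohm, z_imag_ohm``
* Fit report: ``device_id, day, r1_ohm, rb_ohm, cp_farad, q_cpe, alpha,
  residual_norm, converged``
* TEER: ``well_id, group, day, reading_index, raw_ohm, blank_ohm, area_cm2``
* Ussing: ``time_s, current_a`` preceded by ``# clamp_voltage_v=...`` and
  ``# area_cm2=...`` comment lines
* Calcium switch: ``replicate_id, platform, phase, value``
* Trajectory report: ``device_id, day, zmag100_ohm, rb_ohm, r1_ohm, qc_pass``
* Circuit parameters: flat JSON with keys ``r1_ohm, rb_ohm, cp_farad,
  q_cpe, alpha``
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circuit import CircuitParams, FrequencyGrid, ImpedanceSpectrum
from .errors import DomainError, FileFormatError
from .fitting import FitFailure, FitResult, fit_cohort
from .readouts import (
    QC_DAY,
    QC_THRESHOLD_OHM,
    TeerRecord,
    UssingTrace,
    build_trajectories,
    endpoint_test,
    qc_filter,
    teer_group_summary,
)
from .switchstats import PHASES, CalciumSwitchSeries, compare_phases, normalize, platform_summary
from .synth import EisCohortSpec, SwitchCohortSpec, gen_eis_cohort, gen_switch_cohort

__all__ = [
    "read_spectra", "write_spectra", "read_params", "write_params",
    "write_fit_report", "read_teer", "write_teer", "read_ussing",
    "write_ussing", "read_switch", "write_switch", "write_trajectory_report",
    "RunConfig", "run_pipeline",
]

_FLOAT_FMT = "%.17g"


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header + 1-based
            raise FileFormatError(f"{path}: malformed value in column {c!r} at line {line}")
        if coerced.isna().any():
            line = int(df.index[coerced.isna()][0]) + 2
            raise FileFormatError(f"{path}: missing value in column {c!r} at line {line}")
        df[c] = coerced
    return df


def write_spectra(spectra, path) -> None:
    rows = []
    for sp in spectra:
        for f, z in zip(sp.frequencies, sp.z):
            rows.append((sp.device_id, sp.day, f, z.real, z.imag))
    df = pd.DataFrame(rows, columns=["device_id", "day", "frequency_hz", "z_real_ohm", "z_imag_ohm"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spectra(path) -> list:
    """Parse a spectra CSV into :class:`ImpedanceSpectrum` objects.

    Rows are grouped by ``(device_id, day)`` and sorted by descending
    frequency; spectrum invariants are validated per group.
    """
    df = pd.read_csv(path, dtype={"device_id": str}, float_precision="round_trip")
    _require_columns(df, ["device_id", "day", "frequency_hz", "z_real_ohm", "z_imag_ohm"], path)
    df = _numeric(df, ["day", "frequency_hz", "z_real_ohm", "z_imag_ohm"], path)
    out = []
    for (dev, day), g in df.groupby(["device_id", "day"], sort=True):
        g = g.sort_values("frequency_hz", ascending=False)
        try:
            grid = FrequencyGrid(tuple(g["frequency_hz"]))
        except DomainError as exc:
            raise FileFormatError(f"{path}: invalid grid for device {dev} day {day}: {exc}") from exc
        z = g["z_real_ohm"].to_numpy() + 1j * g["z_imag_ohm"].to_numpy()
        out.append(ImpedanceSpectrum(grid=grid, z=z, device_id=str(dev), day=int(day)))
    return out


def write_params(params: CircuitParams, path) -> None:
    Path(path).write_text(
        json.dumps(
            {"r1_ohm": params.r1, "rb_ohm": params.rb, "cp_farad": params.cp,
             "q_cpe": params.q, "alpha": params.alpha},
            indent=2,
        )
        + "\n"
    )


def read_params(path) -> CircuitParams:
    d = json.loads(Path(path).read_text())
    try:
        return CircuitParams(
            r1=float(d["r1_ohm"]), rb=float(d["rb_ohm"]), cp=float(d["cp_farad"]),
            q=float(d["q_cpe"]), alpha=float(d["alpha"]),
        )
    except KeyError as exc:
        raise FileFormatError(f"{path}: missing parameter key {exc}") from exc


def write_fit_report(results, path) -> None:
    """One row per device/day; failures carry NaN parameters."""
    rows = []
    for r in results:
        if isinstance(r, FitFailure):
            rows.append(
                {"device_id": r.device_id, "day": r.day, "r1_ohm": np.nan,
                 "rb_ohm": np.nan, "cp_farad": np.nan, "q_cpe": np.nan,
                 "alpha": np.nan, "residual_norm": np.nan, "converged": False}
            )
        else:
            p = r.params
            rows.append(
                {"device_id": r.device_id, "day": r.day, "r1_ohm": p.r1,
                 "rb_ohm": p.rb, "cp_farad": p.cp, "q_cpe": p.q, "alpha": p.alpha,
                 "residual_norm": r.residual_norm, "converged": r.converged}
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_teer(records, path) -> None:
    rows = [
        (r.well_id, r.group, r.day, r.reading_index, r.raw_ohm, r.blank_ohm, r.area_cm2)
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["well_id", "group", "day", "reading_index", "raw_ohm", "blank_ohm", "area_cm2"]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_teer(path) -> list:
    df = pd.read_csv(path, dtype={"well_id": str, "group": str}, float_precision="round_trip")
    _require_columns(df, ["well_id", "group", "day", "reading_index", "raw_ohm", "blank_ohm", "area_cm2"], path)
    df = _numeric(df, ["day", "reading_index", "raw_ohm", "blank_ohm", "area_cm2"], path)
    return [
        TeerRecord(
            well_id=r.well_id, group=r.group, day=int(r.day),
            raw_ohm=float(r.raw_ohm), blank_ohm=float(r.blank_ohm),
            area_cm2=float(r.area_cm2), reading_index=int(r.reading_index),
        )
        for r in df.itertuples()
    ]


def write_ussing(trace: UssingTrace, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# clamp_voltage_v={trace.clamp_voltage_v!r}\n")
        fh.write(f"# area_cm2={trace.area_cm2!r}\n")
        fh.write("time_s,current_a\n")
        for t, i in zip(trace.time_s, trace.current_a):
            fh.write(f"{t:.17g},{i:.17g}\n")


def read_ussing(path) -> UssingTrace:
    meta = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines(keepends=True)
    n_comment = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, val = line[1:].strip().partition("=")
        meta[key.strip()] = float(val)
        n_comment += 1
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[n_comment:])), float_precision="round_trip")
    _require_columns(df, ["time_s", "current_a"], path)
    df = _numeric(df, ["time_s", "current_a"], path)
    return UssingTrace(
        time_s=df["time_s"].to_numpy(),
        current_a=df["current_a"].to_numpy(),
        clamp_voltage_v=meta.get("clamp_voltage_v", 5e-3),
        area_cm2=meta.get("area_cm2", 0.33),
    )


def write_switch(series, path) -> None:
    rows = [
        (s.replicate_id, s.platform, ph, getattr(s, ph))
        for s in series
        for ph in PHASES
    ]
    pd.DataFrame(rows, columns=["replicate_id", "platform", "phase", "value"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_switch(path) -> list:
    df = pd.read_csv(
        path, dtype={"replicate_id": str, "platform": str, "phase": str},
        float_precision="round_trip",
    )
    _require_columns(df, ["replicate_id", "platform", "phase", "value"], path)
    df = _numeric(df, ["value"], path)
    bad = ~df["phase"].isin(PHASES)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise FileFormatError(f"{path}: unknown phase at line {line}")
    out = []
    for (rid, platform), g in df.groupby(["replicate_id", "platform"], sort=True):
        vals = dict(zip(g["phase"], g["value"]))
        missing = [ph for ph in PHASES if ph not in vals]
        if missing:
            raise FileFormatError(
                f"{path}: replicate {rid} missing phase(s) {missing}"
            )
        out.append(
            CalciumSwitchSeries(
                replicate_id=str(rid), platform=str(platform),
                baseline=float(vals["baseline"]), egta=float(vals["egta"]),
                washout=float(vals["washout"]),
            )
        )
    return out


def write_trajectory_report(trajectories, path) -> None:
    rows = []
    for tr in trajectories:
        for day, z, rb, r1 in zip(tr.days, tr.zmag_100hz, tr.rb, tr.r1):
            rows.append((tr.device_id, day, z, rb, r1, tr.qc_pass))
    pd.DataFrame(
        rows, columns=["device_id", "day", "zmag100_ohm", "rb_ohm", "r1_ohm", "qc_pass"]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


@dataclass
class RunConfig:
    """Configuration of the end-to-end synthetic analysis run."""

    out_dir: str
    seed: int = 0
    spectra_path: str | None = None   # fit an existing file instead of generating
    eis: EisCohortSpec = field(default_factory=EisCohortSpec)
    platforms: tuple = ("2D", "3D", "ex-vivo")
    qc_threshold_ohm: float = QC_THRESHOLD_OHM
    qc_day: int = QC_DAY
    alpha: float = 0.05
    family: str = "baseline"

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["eis"] = dict(self.eis.__dict__)
        d["platforms"] = list(self.platforms)
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Generate (or load), fit, QC-filter, test and report.

    Writes ``spectra.csv`` (when generated), ``fits.csv``,
    ``trajectories.csv``, ``switch.csv``, ``switch_summary.csv``,
    ``switch_significance.csv`` and ``run_log.json`` under
    ``config.out_dir``.  Deterministic given the config and seeds.
    Returns a dict of the in-memory products.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
    }

    if config.spectra_path is not None:
        spectra = read_spectra(config.spectra_path)
        truth = None
    else:
        eis_spec = EisCohortSpec(**{**config.eis.__dict__, "seed": config.seed})
        spectra, truth = gen_eis_cohort(eis_spec)
        write_spectra(spectra, out / "spectra.csv")
        truth.to_csv(out / "spectra_truth.csv", index=False, float_format=_FLOAT_FMT)

    if not spectra:
        warnings.warn("empty spectra input; writing empty reports", stacklevel=2)
    fits = fit_cohort(spectra)
    write_fit_report(fits, out / "fits.csv")
    trajectories = build_trajectories(spectra, fits)
    kept, rejected = qc_filter(trajectories, config.qc_threshold_ohm, config.qc_day)
    write_trajectory_report(trajectories, out / "trajectories.csv")
    log["qc"] = {
        "threshold_ohm": config.qc_threshold_ohm,
        "day": config.qc_day,
        "n_kept": len(kept),
        "n_rejected": len(rejected),
        "rejected": [{"device_id": tr.device_id, "reason": reason} for tr, reason in rejected],
    }

    test = None
    day0 = {tr.device_id: tr.value_at_day(0, "rb") for tr in kept if tr.value_at_day(0, "rb") is not None}
    day14 = {tr.device_id: tr.value_at_day(config.qc_day, "rb") for tr in kept if tr.value_at_day(config.qc_day, "rb") is not None}
    if len(day0) >= 2 and len(day14) >= 2:
        test = endpoint_test(day0, day14, paired="auto")
        log["endpoint_test"] = {
            "kind": test.kind, "statistic": test.statistic,
            "pvalue": test.pvalue, "df": test.df,
        }

    all_series = []
    for k, platform in enumerate(config.platforms):
        spec = SwitchCohortSpec.for_platform(platform, seed=config.seed + 1000 + k)
        series, _ = gen_switch_cohort(spec)
        all_series.extend(series)
    write_switch(all_series, out / "switch.csv")
    normalized = [normalize(s) for s in all_series]
    summary = platform_summary(normalized)
    summary.to_csv(out / "switch_summary.csv", index=False, float_format=_FLOAT_FMT)
    sig = compare_phases(normalized, family=config.family, alpha=config.alpha)
    sig.to_csv(out / "switch_significance.csv", index=False, float_format=_FLOAT_FMT)

    log["config_hash"] = hashlib.sha256(
        json.dumps(log["config"], sort_keys=True).encode()
    ).hexdigest()
    (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return {
        "spectra": spectra, "truth": truth, "fits": fits,
        "trajectories": trajectories, "kept": kept, "rejected": rejected,
        "endpoint_test": test, "switch_summary": summary, "significance": sig,
        "log": log,
    }
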