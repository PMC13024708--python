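"""Complex non-linear least squares (CNLS) estimation of circuit parameters.

Real and imaginary parts of the model--data mismatch are stacked into one
residual vector and weighted per point by the measured modulus ``|Z|``
("modulus weighting"), the standard choice for spectra spanning orders of
magnitude.  Optimization is bounded trust-region least squares
(scipy ``least_squares``, method ``trf``) in a partially log-transformed
space (log10 for r1, cp, q; linear for rb, which may sit at 0, and alpha).

Bounds bracket physiological device values with wide margins:
r1 in [0.1, 1e4] ohm, rb in [0, 1e4] ohm, cp in [1e-9, 1e-2] F,
q in [1e-7, 10] S*s^alpha, alpha in (0.3, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .circuit import CircuitParams, ImpedanceSpectrum, interp_zmag
from .errors import IdentifiabilityError

__all__ = [
    "BOUNDS",
    "FitResult",
    "FitFailure",
    "fit",
    "initialize",
    "fit_cohort",
    "weighted_residual_norm",
]

#: Parameter bounds in natural units: {name: (lo, hi)}.
BOUNDS = {
    "r1": (0.1, 1e4),
    "rb": (0.0, 1e4),
    "cp": (1e-9, 1e-2),
    "q": (1e-7, 10.0),
    "alpha": (0.3, 1.0),
}

#: Fitted rb below this (ohm) is reported with the ``barrier_absent`` flag,
#: matching cell-free / fibroblast-monoculture devices.
BARRIER_ABSENT_RB = 1e-3

_LN10 = math.log(10.0)


@dataclass
class FitResult:
    """Outcome of one CNLS fit.

    ``residual_norm`` is the weighted sum of squared residuals
    (dimensionless, >= 0).  ``per_param_se`` holds asymptotic standard
    errors from the Jacobian at the optimum, in natural parameter units.
    """

    params: CircuitParams
    residual_norm: float
    per_param_se: dict
    converged: bool
    n_iter: int
    weighting: str = "modulus"
    barrier_absent: bool = False
    message: str = ""
    device_id: str = "sim"
    day: int = 0


@dataclass
class FitFailure:
    """A per-device failure recorded (not raised) by :func:`fit_cohort`."""

    device_id: str
    day: int
    reason: str
    converged: bool = False


def _to_internal(p: CircuitParams) -> np.ndarray:
    return np.array([math.log10(p.r1), p.rb, math.log10(p.cp), math.log10(p.q), p.alpha])


def _from_internal(x: np.ndarray) -> CircuitParams:
    return CircuitParams(
        r1=10.0 ** x[0], rb=float(x[1]), cp=10.0 ** x[2], q=10.0 ** x[3], alpha=float(x[4])
    )


_LO = np.array(
    [math.log10(BOUNDS["r1"][0]), BOUNDS["rb"][0], math.log10(BOUNDS["cp"][0]),
     math.log10(BOUNDS["q"][0]), BOUNDS["alpha"][0] + 1e-9]
)
_HI = np.array(
    [math.log10(BOUNDS["r1"][1]), BOUNDS["rb"][1], math.log10(BOUNDS["cp"][1]),
     math.log10(BOUNDS["q"][1]), BOUNDS["alpha"][1]]
)


def _clip_internal(x: np.ndarray) -> np.ndarray:
    return np.clip(x, _LO, _HI)


def _residuals(x: np.ndarray, w_ang: np.ndarray, z: np.ndarray, wts: np.ndarray) -> np.ndarray:
    r1 = 10.0 ** x[0]
    rb = x[1]
    cp = 10.0 ** x[2]
    q = 10.0 ** x[3]
    alpha = x[4]
    zm = r1 + rb / (1.0 + 1j * w_ang * rb * cp) + 1.0 / (q * np.power(1j * w_ang, alpha))
    d = (zm - z) / wts
    return np.concatenate([d.real, d.imag])


def weighted_residual_norm(spectrum: ImpedanceSpectrum, params: CircuitParams) -> float:
    """Modulus-weighted sum of squared residuals of ``params`` on a spectrum."""
    w = 2.0 * np.pi * spectrum.frequencies
    r = _residuals(_to_internal(params), w, spectrum.z, np.abs(spectrum.z))
    return float(np.dot(r, r))


def initialize(spectrum: ImpedanceSpectrum) -> CircuitParams:
    """Heuristic starting point read off the magnitude spectrum.

    r1 from the high-frequency limit; rb from the mid-band plateau (|Z| at
    10 Hz, or the lowest in-span frequency above it) minus r1, floored at
    1 ohm; alpha = 0.8; q from the low-frequency CPE-dominated point;
    cp = 1 uF.  Always returns an in-bounds parameter vector.
    """
    freqs = spectrum.frequencies
    mags = spectrum.zmag
    r1 = float(mags[0])
    f_plateau = 10.0 if freqs[-1] <= 10.0 <= freqs[0] else freqs[-1]
    z_plateau = interp_zmag(spectrum, f_plateau)
    rb = max(z_plateau - r1, 1.0)
    alpha = 0.8
    f_lo = freqs[-1]
    z_lo = float(mags[-1])
    q = 1.0 / (z_lo * (2.0 * np.pi * f_lo) ** alpha)
    cp = 1e-6
    x = _clip_internal(np.array([math.log10(max(r1, BOUNDS["r1"][0])), rb,
                                 math.log10(cp), math.log10(max(q, BOUNDS["q"][0])), alpha]))
    return _from_internal(x)


def _check_identifiable(spectrum: ImpedanceSpectrum) -> None:
    freqs = spectrum.frequencies
    if len(freqs) < 10:
        raise IdentifiabilityError(
            f"spectrum has {len(freqs)} points; >= 10 required"
        )
    span = math.log10(freqs[0] / freqs[-1])
    if span < 2.0:
        raise IdentifiabilityError(
            f"spectrum spans {span:.2f} decades; >= 2 required"
        )


def fit(
    spectrum: ImpedanceSpectrum,
    init: CircuitParams | None = None,
    multistart: int = 0,
    seed: int | None = None,
    max_iter: int = 500,
) -> FitResult:
    """Fit the equivalent circuit to one spectrum.

    Parameters
    ----------
    spectrum : ImpedanceSpectrum
        Must have >= 10 points spanning >= 2 decades.
    init : CircuitParams, optional
        Starting point; the heuristic initializer is used when absent.
    multistart : int
        Number of additional perturbed (seeded) restarts attempted when the
        deterministic start does not converge.
    seed : int, optional
        Seed for the multistart perturbations.
    max_iter : int
        Iteration cap for the trust-region optimizer.

    Raises
    ------
    IdentifiabilityError
        Too few points or too narrow a frequency span.
    """
    _check_identifiable(spectrum)
    if init is None:
        init = initialize(spectrum)
    w = 2.0 * np.pi * spectrum.frequencies
    z = spectrum.z
    wts = np.abs(z)

    def solve(x0: np.ndarray):
        return least_squares(
            _residuals, _clip_internal(x0), args=(w, z, wts),
            bounds=(_LO, _HI), method="trf",
            ftol=1e-12, xtol=1e-12, gtol=1e-12,
            max_nfev=max_iter * (len(x0) + 1),
        )

    res = solve(_to_internal(init))
    n_iter = int(res.nfev)
    if not res.success and multistart > 0:
        rng = np.random.default_rng(seed)
        best = res
        x0 = _to_internal(init)
        for _ in range(multistart):
            pert = x0 + rng.normal(scale=[0.15, 0.0, 0.3, 0.3, 0.0], size=5)
            pert[1] = x0[1] * rng.uniform(0.5, 2.0)
            pert[4] = np.clip(x0[4] + rng.normal(scale=0.05), _LO[4], _HI[4])
            cand = solve(pert)
            n_iter += int(cand.nfev)
            if cand.cost < best.cost:
                best = cand
        res = best

    params = _from_internal(res.x)
    residual_norm = float(2.0 * res.cost)
    se = _standard_errors(res.jac, res.cost, params)
    return FitResult(
        params=params,
        residual_norm=residual_norm,
        per_param_se=se,
        converged=bool(res.success),
        n_iter=n_iter,
        barrier_absent=params.rb < BARRIER_ABSENT_RB,
        message=str(res.message),
        device_id=spectrum.device_id,
        day=spectrum.day,
    )


def _standard_errors(jac: np.ndarray, cost: float, params: CircuitParams) -> dict:
    m, p = jac.shape
    dof = max(m - p, 1)
    s2 = 2.0 * cost / dof
    try:
        cov = s2 * np.linalg.pinv(jac.T @ jac)
        se_int = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
        se_int = np.full(p, np.nan)
    # delta method back to natural units for the log10-transformed params
    scale = np.array([params.r1 * _LN10, 1.0, params.cp * _LN10, params.q * _LN10, 1.0])
    se = se_int * scale
    return dict(zip(("r1", "rb", "cp", "q", "alpha"), (float(v) for v in se)))


def fit_cohort(spectra, **fit_kwargs):
    """Fit every spectrum in a cohort, recording failures per device.

    Returns a list (order-preserving, same length as the input) whose
    elements are :class:`FitResult` or :class:`FitFailure`; identifiability
    problems are routed to :class:`FitFailure` rather than raised.
    """
    out = []
    for sp in spectra:
        try:
            out.append(fit(sp, **fit_kwargs))
        except IdentifiabilityError as exc:
            out.append(FitFailure(device_id=sp.device_id, day=sp.day, reason=str(exc)))
    return out
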