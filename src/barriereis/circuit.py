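"""Forward model of the e-transmembrane device impedance.

The device is modeled by the standard transmembrane-barrier equivalent
circuit: an electrolyte series resistance ``R1``, the epithelial barrier as
a parallel resistance--capacitance pair ``(Rb || Cp)``, and a constant phase
element (CPE) in series representing the porous conducting-polymer scaffold
and the rest of the electrode system::

    Z(omega) = R1 + Rb / (1 + j*omega*Rb*Cp) + 1 / (Q * (j*omega)**alpha)

with ``omega = 2*pi*f``.  The CPE convention is ``Z_CPE = 1/(Q (j w)^alpha)``
with ``j**alpha = exp(j*alpha*pi/2)`` (principal branch), the dominant
convention in the impedance literature.  Capacitive impedance carries a
negative imaginary part; Nyquist plots should show ``-Im(Z)``.

This is a small-signal linear model: the DC bias and AC amplitude used
during acquisition are metadata only and do not enter the impedance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = [
    "CircuitParams",
    "FrequencyGrid",
    "ImpedanceSpectrum",
    "impedance",
    "simulate_spectrum",
    "make_frequency_grid",
    "interp_zmag",
]

#: Default acquisition metadata (bias and AC amplitude, volts).
DEFAULT_META = {"bias_v": 0.1, "ac_amplitude_v": 0.01}


@dataclass(frozen=True)
class CircuitParams:
    """Parameter vector of the barrier equivalent circuit.

    Parameters
    ----------
    r1 : float
        Electrolyte (series) resistance, ohm.  ``r1 >= 0``.
    rb : float
        Epithelial barrier resistance, ohm.  ``rb >= 0``; ``rb = 0`` is the
        cell-free / no-barrier limit.
    cp : float
        Barrier capacitance, farad.  ``cp > 0``.
    q : float
        CPE magnitude, S*s^alpha.  ``q > 0``.
    alpha : float
        CPE exponent, dimensionless, ``0 < alpha <= 1``; ``alpha = 1``
        reduces the CPE to an ideal capacitor.
    """

    r1: float
    rb: float
    cp: float
    q: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.r1 >= 0):
            raise DomainError(f"r1 must be >= 0, got {self.r1}")
        if not (self.rb >= 0):
            raise DomainError(f"rb must be >= 0, got {self.rb}")
        if not (self.cp > 0):
            raise DomainError(f"cp must be > 0, got {self.cp}")
        if not (self.q > 0):
            raise DomainError(f"q must be > 0, got {self.q}")
        if not (0 < self.alpha <= 1):
            raise DomainError(f"alpha must be in (0, 1], got {self.alpha}")

    def as_array(self) -> np.ndarray:
        return np.array([self.r1, self.rb, self.cp, self.q, self.alpha])

    @classmethod
    def from_array(cls, x) -> "CircuitParams":
        r1, rb, cp, q, alpha = (float(v) for v in x)
        return cls(r1=r1, rb=rb, cp=cp, q=q, alpha=alpha)


@dataclass(frozen=True)
class FrequencyGrid:
    """A strictly descending grid of positive frequencies in Hz."""

    frequencies: tuple

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise DomainError("frequency grid must be a non-empty 1-D sequence")
        if np.any(f <= 0):
            raise DomainError("all frequencies must be > 0")
        if f.size > 1 and not np.all(np.diff(f) < 0):
            raise DomainError("frequencies must be strictly descending")
        object.__setattr__(self, "frequencies", tuple(float(v) for v in f))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.frequencies, dtype=float)

    def __len__(self) -> int:
        return len(self.frequencies)

    @classmethod
    def default(cls) -> "FrequencyGrid":
        """61-point sweep, 1e5 Hz down to 0.1 Hz, 10 points per decade.

        100.0 Hz falls exactly on the grid (exponent 5 - 30/10 = 2).
        """
        return make_frequency_grid(1e5, 0.1, 10)


def make_frequency_grid(f_max: float, f_min: float, points_per_decade: int) -> FrequencyGrid:
    """Log-uniform descending grid from ``f_max`` down to ``f_min``.

    Both endpoints are included.  The span is rounded to the nearest whole
    number of grid steps; decade-aligned frequencies (e.g. 100 Hz on the
    default sweep) are exact because exponents are formed as
    ``log10(f_max) - k / points_per_decade``.
    """
    if f_min <= 0 or f_max <= 0:
        raise DomainError("frequency bounds must be positive")
    if f_max < f_min:
        raise DomainError(f"f_max ({f_max}) must be >= f_min ({f_min})")
    if points_per_decade < 1:
        raise DomainError("points_per_decade must be >= 1")
    if f_max == f_min:
        return FrequencyGrid((float(f_max),))
    n_dec = math.log10(f_max / f_min)
    n = int(round(n_dec * points_per_decade)) + 1
    exps = math.log10(f_max) - np.arange(n, dtype=float) / points_per_decade
    freqs = np.power(10.0, exps)
    freqs[0] = f_max
    freqs[-1] = f_min
    return FrequencyGrid(tuple(freqs))


@dataclass
class ImpedanceSpectrum:
    """One device/day impedance sweep.

    ``day`` runs on the co-culture clock (day 0 = epithelial seeding,
    which is total-culture day 6 for the 3D device).
    """

    grid: FrequencyGrid
    z: np.ndarray
    device_id: str = "sim"
    day: int = 0
    meta: dict = field(default_factory=lambda: dict(DEFAULT_META))

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=complex)
        if z.ndim != 1 or z.size != len(self.grid):
            raise DomainError(
                f"z has length {z.size}, grid has length {len(self.grid)}"
            )
        self.z = z

    @property
    def frequencies(self) -> np.ndarray:
        return self.grid.as_array()

    @property
    def zmag(self) -> np.ndarray:
        return np.abs(self.z)

    def __len__(self) -> int:
        return len(self.grid)


def impedance(params: CircuitParams, f):
    """Complex impedance of the circuit at frequency ``f`` (Hz).

    Accepts a scalar or array of positive frequencies; returns a complex
    scalar or array.  ``Im(Z) <= 0`` everywhere and ``Z -> r1`` as
    ``f -> inf``.
    """
    farr = np.asarray(f, dtype=float)
    if np.any(farr <= 0) or not np.all(np.isfinite(farr)):
        raise DomainError("frequency must be positive and finite")
    w = 2.0 * np.pi * farr
    z_barrier = params.rb / (1.0 + 1j * w * params.rb * params.cp)
    z_cpe = 1.0 / (params.q * np.power(1j * w, params.alpha))
    z = params.r1 + z_barrier + z_cpe
    if np.isscalar(f):
        return complex(z)
    return z


def simulate_spectrum(
    params: CircuitParams,
    grid: FrequencyGrid | None = None,
    device_id: str = "sim",
    day: int = 0,
    meta: dict | None = None,
) -> ImpedanceSpectrum:
    """Evaluate the forward model over a grid (default: 61-point sweep)."""
    if grid is None:
        grid = FrequencyGrid.default()
    z = impedance(params, grid.as_array())
    return ImpedanceSpectrum(
        grid=grid,
        z=np.atleast_1d(z),
        device_id=device_id,
        day=day,
        meta=dict(DEFAULT_META) if meta is None else dict(meta),
    )


def interp_zmag(spectrum: ImpedanceSpectrum, f: float) -> float:
    """|Z| at frequency ``f``: exact grid hit, else log-linear interpolation.

    |Z| is interpolated linearly against log10(f) between the bracketing
    grid points (the way a magnitude plot is read).  ``f`` outside the grid
    span is a :class:`DomainError`.
    """
    freqs = spectrum.frequencies
    mags = spectrum.zmag
    if f <= 0:
        raise DomainError("frequency must be positive")
    hit = np.isclose(freqs, f, rtol=1e-9, atol=0.0)
    if hit.any():
        return float(mags[np.argmax(hit)])
    if f > freqs[0] or f < freqs[-1]:
        raise DomainError(
            f"{f} Hz outside grid span [{freqs[-1]}, {freqs[0]}] Hz"
        )
    # grid is descending; np.interp needs ascending
    lf = np.log10(freqs[::-1])
    lm = mags[::-1]
    return float(np.interp(math.log10(f), lf, lm))
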