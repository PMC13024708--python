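"""Static Nyquist / Bode / trajectory figures (matplotlib)."""

from __future__ import annotations

import numpy as np


def nyquist(spectrum, ax=None, **kwargs):
    """Nyquist plot: -Im(Z) against Re(Z) (capacitive convention)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(spectrum.z.real, -spectrum.z.imag, marker="o", ms=3, **kwargs)
    ax.set_xlabel(r"Re(Z) [$\Omega$]")
    ax.set_ylabel(r"$-$Im(Z) [$\Omega$]")
    ax.set_aspect("equal", adjustable="datalim")
    return ax


def bode(spectrum, axes=None, **kwargs):
    """Bode magnitude and phase against frequency (log-x)."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True)
    f = spectrum.frequencies
    axes[0].loglog(f, spectrum.zmag, **kwargs)
    axes[0].set_ylabel(r"|Z| [$\Omega$]")
    axes[1].semilogx(f, np.degrees(np.angle(spectrum.z)), **kwargs)
    axes[1].set_ylabel("phase [deg]")
    axes[1].set_xlabel("frequency [Hz]")
    return axes


def trajectory(trajectories, column="rb", ax=None, **kwargs):
    """Per-device time course of ``rb``, ``r1`` or ``zmag_100hz``."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for tr in trajectories:
        ax.plot(tr.days, getattr(tr, column), marker="o", label=tr.device_id, **kwargs)
    ax.set_xlabel("co-culture day")
    labels = {"rb": r"$R_b$ [$\Omega$]", "r1": r"$R_1$ [$\Omega$]",
              "zmag_100hz": r"|Z|(100 Hz) [$\Omega$]"}
    ax.set_ylabel(labels.get(column, column))
    return ax
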