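# barriereis

Electrical analysis of intestinal epithelial barrier integrity across
three measurement platforms: a 3D bioelectronic transmembrane device
with a conducting-polymer (PEDOT:PSS) scaffold monitored by
electrochemical impedance spectroscopy (EIS), conventional 2D insert
cultures read by voltohmmeter (TEER), and ex vivo intestinal segments in
an Ussing chamber.  The package is for bioelectronics and barrier-biology
groups who need the full chain from raw electrical readouts to
cross-platform statistics — plus synthetic generators that emulate all
three modalities so the entire pipeline runs and is testable without any
instrument data.

## The model and statistics at its core

The 3D device impedance is modeled by the standard transmembrane-barrier
equivalent circuit

```
Z(ω) = R1 + Rb/(1 + jω·Rb·Cp) + 1/(Q·(jω)^α),   ω = 2πf
```

where R1 is the electrolyte resistance, Rb and Cp the resistance and
capacitance of the epithelial barrier, and (Q, α) a constant phase
element for the porous scaffold.  Rb — the resistive paracellular
pathway — is the figure of merit for barrier formation.  It is estimated
by complex non-linear least squares (CNLS): real and imaginary residuals
stacked, modulus-weighted by |Z| per point, minimized by bounded
trust-region least squares.

Around the fit, the package provides:

* the |Z|(100 Hz) trajectory metric and the day-14 quality-control rule
  (|Z|(100 Hz) ≥ 95 Ω) that gates device inclusion;
* TEER conversion `(raw − blank) · 0.33 cm²` with group summaries;
* Ussing-chamber resistance `R = V/ΔI` from clamped-voltage traces with
  an explicit baseline-equilibrium criterion;
* the EGTA calcium-switch analysis: per-replicate baseline
  normalization, one-way ANOVA and Holm–Šídák-adjusted baseline-vs-phase
  comparisons per platform, with "recovery" defined as non-significance
  of baseline-vs-washout at α = 0.05.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

`examples/01_simulate_and_fit.py` simulates a noiseless device spectrum
on the default 61-point sweep (10⁵ → 0.1 Hz) and recovers its parameters
by CNLS from the heuristic initializer:

```
converged: True (weighted residual norm 5.76e-31)
 param        truth       fitted         se
    r1           60           60      1e-15
    rb           25           25    1.6e-15
    cp        5e-06        5e-06      8e-22
     q        0.002        0.002    4.9e-20
 alpha         0.85         0.85    1.3e-17
```

All five parameters return to numerical precision — the fit is
self-consistent on clean data.  `examples/02_barrier_growth_trajectory.py`
runs the full cohort pipeline (generate → fit → QC → endpoint test) on a
10-device synthetic cohort whose barrier grows from 14.97 Ω to 25.37 Ω
over 14 co-culture days:

```
devices kept by QC: 10, rejected: 0
mean fitted Rb day 0:   14.60 ohm
mean fitted Rb day 14:  25.34 ohm
paired t = -13.26, p = 3.3e-07
```

The fitted barrier resistance rises significantly as the epithelium
matures.  The remaining examples cover the TEER summary, the
Ussing-chamber readout and the three-platform calcium-switch comparison;
each prints a short explanation of its numbers.

A thin CLI mirrors the library for batch work:

```sh
barrier-eis synth eis --out data/ --seed 1
barrier-eis fit-eis --in data/spectra.csv --out fits.csv
barrier-eis run-all --out run/ --seed 1
```

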