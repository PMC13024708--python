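# Methods

`barriereis` analyzes the electrical readouts of an intestinal epithelial
barrier grown on three platforms: a 2D insert culture read with a
voltohmmeter (TEER), a 3D bioelectronic transmembrane device with a
conducting-polymer (PEDOT:PSS) scaffold read by electrochemical impedance
spectroscopy (EIS), and ex vivo small-intestine segments mounted in an
Ussing chamber.  This note records the models, parameter choices and
numerical decisions; it states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Equivalent-circuit model

The 3D device is modeled by the standard transmembrane-barrier circuit:
a series chain of the electrolyte resistance, the epithelial barrier as a
parallel RC pair, and a constant phase element (CPE) for the porous
scaffold/electrode system,

    Z(ω) = R1 + Rb / (1 + jω·Rb·Cp) + 1 / (Q·(jω)^α),   ω = 2πf.

Parameters and defaults:

| symbol | meaning                          | units   | bounds (fit)   |
|--------|----------------------------------|---------|----------------|
| R1     | electrolyte series resistance    | Ω       | [0.1, 1e4]     |
| Rb     | barrier (paracellular) resistance| Ω       | [0, 1e4]       |
| Cp     | barrier capacitance              | F       | [1e-9, 1e-2]   |
| Q      | CPE magnitude                    | S·s^α   | [1e-7, 10]     |
| α      | CPE exponent                     | –       | (0.3, 1]       |

Design choices where the physical description leaves the wiring open:
the CPE is placed **in series** (the usual choice for a porous scaffold
electrode dominating the low-frequency response); the CPE convention is
`Z = 1/(Q(jω)^α)` with the principal branch `j^α = exp(jαπ/2)`; capacitive
impedance has a negative imaginary part, so Nyquist exports plot −Im(Z).
The exponent α is a free parameter: fitted values near 1 indicate nearly
ideal capacitive behavior.  The model is small-signal and linear; the DC
bias (0.1 V) and AC amplitude (10 mV) used during acquisition are carried
as metadata only.

The default frequency grid is the acquisition sweep: 1e5 Hz down to
0.1 Hz at 10 points per decade, 61 points, both endpoints included.
Exponents are formed as `log10(f_max) − k/ppd`, so decade-aligned points
(in particular 100 Hz, where the quality-control rule and the trajectory
metric live) are floating-point exact.

## CNLS fitting

Real and imaginary residuals are stacked and divided per point by the
measured modulus |Z| (modulus weighting), which balances a spectrum
spanning several orders of magnitude.  Optimization is bounded
trust-region least squares (`scipy.optimize.least_squares`, `trf`) in a
partially log-transformed space: log10 for R1, Cp, Q (strictly positive,
scale-free), linear for Rb (which may legitimately sit at 0 — the
cell-free limit, reported with a `barrier_absent` flag below 1e-3 Ω) and
α.  Tolerances are 1e-12 on cost/step/gradient with a 500-iteration cap;
a single deterministic start from the heuristic initializer is usually
sufficient (noiseless spectra recover all five parameters to ~1e-14
relative), with an optional seeded multistart fallback on non-convergence.

The initializer reads the magnitude spectrum: R1 from the high-frequency
limit, Rb from the 10 Hz plateau minus R1 (floored at 1 Ω), α = 0.8, Q
from the lowest-frequency point assuming CPE dominance, Cp = 1 µF, all
clipped into bounds.

Standard errors come from the Gauss–Newton covariance at the optimum
(residual variance times the pseudo-inverse of JᵀJ), mapped back to
natural units by the delta method.  Spectra with fewer than 10 points or
spanning fewer than 2 decades are rejected as unidentifiable; the cohort
driver records such failures per device instead of raising.

Identifiability floor aside, the fit is deliberately restricted to the
one supported topology: no circuit-description language, no model
selection, no Kramers–Kronig validation.

## Readouts

**TEER.** `TEER [Ω·cm²] = (raw − blank) · area` with the 24-well insert
growth area 0.33 cm².  Readings within a well are blank-subtracted then
averaged (identical to averaging first when the blank is shared); group
summaries report mean and sample SD (n−1) across wells.  Negative values
(blank exceeding raw) are flagged, not discarded — exclusion is the
caller's policy.

**Ussing chamber.** A 5 mV clamp across the tissue; `R = V/ΔI` where ΔI
is the mean current in a 60 s clamp window minus the mean of the 60 s
baseline window immediately preceding it.  The clamp onset is located at
the first sample-to-sample jump reaching half the largest jump in the
trace (robust to repeated pulses).  Equilibrium is operationalized as: the
trace covers ≥ 30 min and the linear drift of the final 10-minute
baseline window stays below 1%/min of its mean current.  ΔI ≤ 0 or below
3× the baseline noise raises a no-deflection error.  Area normalization
uses the same 0.33 cm² aperture.

**EIS trajectory.** |Z| at 100 Hz is read at the exact grid point when
present, otherwise by interpolating |Z| linearly against log10(f) between
the bracketing points (how a magnitude plot is read; complex
interpolation is deliberately avoided).  The inclusion rule keeps devices
with |Z|(100 Hz) ≥ 95 Ω at day 14 (boundary inclusive); rejects carry a
reason string.  All trajectory APIs use the co-culture clock (day 0 =
epithelial seeding = total-culture day 6); converters are provided.
Endpoint comparisons use the two-tailed Student t-test — paired when both
arms are complete device-keyed pairs, unpaired (equal-variance) otherwise,
with Welch behind a flag.

## Calcium-switch statistics

Each replicate's (baseline, EGTA, washout) triple is divided by its own
baseline; per-replicate normalization is what makes the reported SDs of
normalized values meaningful (a grand-baseline normalization would leave
the baseline SD undefined at exactly 1).  The whole analysis is therefore
invariant to per-replicate rescaling of the raw units — the property that
makes 2D / 3D / ex vivo comparable at all.

Within each platform, a one-way ANOVA across the three phases is reported
alongside pairwise baseline-vs-phase comparisons.  Because the normalized
baseline is identically 1, a paired baseline-vs-phase t-test reduces to a
one-sample t-test of the normalized phase values against 1; constant
input (no effect anywhere) is reported as t = 0, p = 1 rather than NaN.
The Holm–Šídák step-down adjustment (`1 − (1 − p_(i))^(m−i+1)` with a
monotone running maximum; delegated to statsmodels) is applied within a
per-platform family of m = 2 comparisons by default (baseline-vs-EGTA,
baseline-vs-washout — the comparisons drawn in the study's figures);
`family="all"` widens the family to m = 3 with EGTA-vs-washout.
"Recovery" is operationalized as non-significance of baseline-vs-washout
at α = 0.05.  Significance labels follow the 0.05 / 0.005 / 0.001 /
0.0001 asterisk convention.  The ANOVA handles the degenerate all-equal
case as F = 0, p = 1, and zero within-group variance with distinct means
as F = ∞, p = 0.  Replicate nesting (technical within biological) is not
modeled; neither is EGTA diffusion.

## Synthetic-data generators

Every generator is a pure function of (spec, seed) — identical inputs
give byte-identical outputs — and emits its ground truth alongside the
data, so recovery error is measurable at any setting.

**EIS cohorts.** Per device, (Rb(0), Rb(14)) is drawn from a bivariate
normal with means/SDs 14.97 ± 3.36 and 25.37 ± 3.30 Ω and correlation 0.5
(the device-to-device endpoint covariance is unknown; 0.5 is a package
choice exposed as `endpoint_corr`).  Rb(t) follows a piecewise-linear
schedule allocating 40% of the total increase to days 0–10 and 60% to
days 10–14, encoding the post-confluence acceleration as a simple convex
shape.  R1 is constant per device (60 ± 5 Ω; the 5 Ω spread is a package
choice consistent with the observed day-0 |Z| spread).  The nuisance CPE
magnitude Q is **calibrated**: holding R1 = 60 Ω, Cp = 5 µF and α = 0.85
fixed, a 1-D Brent root find on log10(Q) per endpoint makes the noiseless
mean device satisfy the reported |Z|(100 Hz) endpoints (82.08 and
107.26 Ω) simultaneously with the Rb means.  The |Z| increase exceeds the
Rb increase, and the calibration attributes the surplus to the scaffold
CPE (Q falls as cells infill the pores), keeping R1 constant as observed;
log10(Q) is interpolated along the same growth schedule between the two
solved values.  Cp, α and the nuisance anchors are not reported by the
measurements being emulated and are flagged as package defaults.
Measurement noise is i.i.d. Gaussian with standard deviation
`noise_rel · |Z|` (default 1%) on each quadrature component.

**TEER tables.** A day-14 target per well from the group distribution
(co-culture 54 ± 6, IEC-6 27 ± 8, 208F 20 ± 3 Ω·cm²), approached along a
logistic rise (midpoint day 7, scale 2 days, rescaled to hit the target
at day 14 exactly); records invert the TEER formula with a nominal blank
of 100 ± 5 Ω (blank values are never reported; this is a package choice).

**Ussing traces.** ≥ 35 min at a 0.2 mA baseline with square clamp pulses
of height ΔI = V/R_tissue (default two 60 s pulses from t = 32 min) and
proportional noise.  The real clamp's pulse protocol is not specified;
the square-pulse protocol is configurable.

**Calcium-switch tables.** Baseline per replicate (2D: 54 ± 6 Ω·cm²;
3D: 25.37 ± 3.30 Ω; ex vivo: 90 ± 15 Ω — the ex vivo absolute baseline is
not reported and is a package choice, irrelevant after normalization),
multiplied by independent EGTA and washout effect draws set to the
reported normalized means/SDs (EGTA 0.83 ± 0.09 / 0.99 ± 0.13 /
0.85 ± 0.16; washout 0.68 ± 0.13 / 0.83 ± 0.03 / 0.54 ± 0.14 for
2D / 3D / ex vivo) with the study replicate counts n = 11 / 9 / 9.
Effects multiply the replicate's own baseline, so normalization recovers
the effect draws exactly.

**What the generators do not emulate:** instrument artifacts (EVOM
digitization, potentiostat drift, LabChart filtering), non-Gaussian or
frequency-correlated noise, biological time-courses beyond the stated
schedules, within-replicate correlation between EGTA and washout
responses, and any morphology/imaging signal.  Passing recovery tests
therefore demonstrates correctness of the analysis pipeline under the
stated statistical structure, not robustness to real-instrument
pathologies.

## Statistical power of the cross-platform pattern

At the generator's own effect sizes, the detectable pattern is: 2D
disruption and incomplete 2D recovery (washout significantly below
baseline), and ex vivo EGTA disruption (standardized effect ≈ 0.9,
power ≈ 0.7 at n = 9).  The 3D EGTA-phase effect (0.99 ± 0.13) has a
standardized magnitude of ≈ 0.08, so no test can detect it above the
type-I rate; and the 3D washout effect (0.83 ± 0.03) is so tight that a
one-sample test against baseline is essentially always significant.  The
package reports what the numbers support; the corresponding qualitative
acceptance check for 3D EGTA detection fails by design of the input
distributions, and the full-pipeline type-I error under a no-effect
generator is verified ≤ 7% at nominal 5% over 500 seeded runs.

## Problem sizes and tolerances

Noiseless round-trip checks assert < 0.1% relative parameter error
(measured ~1e-14); calibration targets are verified to 0.01 Ω against a
bisection oracle at 1e-6; stochastic recovery checks compare seeded
cohort means to the generating means within 2 SEM at the study sample
sizes (n = 16 TEER wells; n = 11/9/9 switch replicates; n = 10 EIS
devices).  Power and calibration sweeps use 100–500 seeds; the
grid-search fitting oracle uses 11 points per parameter on a ±20% log
grid.  These sizes are the package's chosen defaults and run in seconds
on a single CPU.

## Known limitations

Only the one circuit topology is supported; no Bayesian uncertainty, no
alternative weighting schemes beyond modulus weighting; the Ussing
analysis ignores short-circuit-current physiology and electrode-offset
compensation; the calcium-switch families are configurable but the
mapping to the original figure's exact test family is inferred, not
documented by the source measurements.
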