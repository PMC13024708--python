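"""Synthetic barrier-growth cohort: generate, fit, QC-filter, test.

Generates a 10-device EIS cohort whose barrier resistance grows from
14.97 ohm (day 0) to 25.37 ohm (day 14) on the co-culture clock, fits
every spectrum, applies the day-14 inclusion rule (|Z|(100 Hz) >= 95 ohm)
and tests the day-0 vs day-14 Rb difference.
"""

import numpy as np

from barriereis import EisCohortSpec, endpoint_test, fit_cohort, gen_eis_cohort, qc_filter
from barriereis.readouts import build_trajectories

spec = EisCohortSpec(n_devices=10, days=(0, 2, 4, 6, 8, 10, 12, 14), seed=42)
spectra, truth = gen_eis_cohort(spec)
fits = fit_cohort(spectra)
trajectories = build_trajectories(spectra, fits)
kept, rejected = qc_filter(trajectories)

print(f"devices kept by QC: {len(kept)}, rejected: {len(rejected)}")
day0 = {t.device_id: t.value_at_day(0, "rb") for t in kept}
day14 = {t.device_id: t.value_at_day(14, "rb") for t in kept}
print(f"mean fitted Rb day 0:  {np.mean(list(day0.values())):6.2f} ohm")
print(f"mean fitted Rb day 14: {np.mean(list(day14.values())):6.2f} ohm")
res = endpoint_test(day0, day14)  # auto-pairs on device ids
print(f"{res.kind} t = {res.statistic:.2f}, p = {res.pvalue:.2g}")
# A small p-value means the fitted barrier resistance rose significantly
# as the epithelium matured -- the device's figure of merit for barrier
# formation.
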