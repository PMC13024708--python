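"""TEER pipeline: voltohmmeter raw/blank readings to group summaries.

Generates a 2D-insert cohort (co-culture plus the two monocultures) with
the day-14 group targets, converts raw/blank pairs to ohm*cm^2 via
(raw - blank) * 0.33, and prints the day-14 group means: the co-culture
barrier should sit about 2.5x above the monocultures.
"""

from barriereis import gen_teer_cohort, teer_group_summary

records, truth = gen_teer_cohort(n_wells=8, seed=7)
summary = teer_group_summary(records)
day14 = summary[summary["day"] == 14]
print(day14.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
# mean/sd in ohm*cm^2 across wells; n_wells wells per group.
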