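"""Reproduce the derived reporting quantities from the published estimates.

Loads the published coefficient table (shipped with the package) and runs
the contrast machinery: the 3x3 slope-effect grid and the
region-difference-by-year projection.
"""

import mtpcost as m

fit = m.reference_fit()

grid = m.named_slope_contrasts(fit)
print("monthly log-mean slope effects (per month of follow-up):")
print(grid.pivot(index="region", columns="period", values="estimate").round(4))
print()
print("the (difference, after-before) cell is the region difference-in-"
      "differences of pre/post slopes: -0.0152, the study's headline effect;")
print("the (difference, after) cell, 0.0026, is the monthly rate at which "
      "the regional cost gap accrues after diagnosis.\n")

print("region difference in overall mean expenditure by year after diagnosis:")
table = m.region_difference_table(fit, years=(1, 2, 3, 4, 5))
print(table.to_string(index=False))
print("(published row: 0.26 / 0.52 / 0.78 / 1.05 / 1.31 percent; years 4-5 "
      "differ in the last digit from the rounded recomputation because the "
      "source rounded from unprinted precision)")
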