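"""Simulate a two-rater width study and run the agreement battery.

Draws an 18-subject, 2-rater, 3-repetition table from the two-way
random-effects model (novice overestimates by 1.3 mm) and reports ICC(2,1)
with its CI and post-hoc power, Bland-Altman limits and the calibration
regression between the raters.
"""

import sasmorph as sm
from sasmorph.phantom import RaterSimSpec

spec = RaterSimSpec(
    n_subjects=18, k_raters=2, n_reps=3,
    subject_mean=11.4, subject_sd=2.0,
    rater_bias=(1.3, 0.0),   # R1 = novice (overestimates), R2 = expert
    error_sd=0.7, seed=1,
)
table, implied_icc = sm.simulate_measurements(spec)
print(f"simulated {len(table)} rows; implied population ICC(2,1) "
      f"= {implied_icc:.3f}")

report = sm.run_agreement(
    sm.PipelineConfig(),
    table,
    [{"name": "novice_vs_expert",
      "a": {"rater": "R1"}, "b": {"rater": "R2"}}],
)
row = report.iloc[0]
print(f"ICC(2,1) = {row.icc:.2f} [{row.ci_low:.2f}-{row.ci_high:.2f}], "
      f"power = {row.power:.2f}, {row.classification}")
print(f"bias = {row.bias:+.2f} mm, LoA [{row.loa_low:.2f}, {row.loa_high:.2f}] mm")
print(f"calibration: expert = {row.intercept:.2f} + {row.slope:.2f} x novice, "
      f"R^2 = {row.r2:.2f}, RMSE = {row.rmse:.2f} mm")

# the fixed 1.3 mm offset depresses the absolute-agreement ICC below the
# value the same data would reach without bias, and shows up as the
# Bland-Altman bias.
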