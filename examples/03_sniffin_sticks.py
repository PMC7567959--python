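"""Simulate the Sniffin' Sticks battery for one cohort.

The threshold is a 2-down-1-up staircase over 16 dilution steps, scored
as the mean of the last 4 of 7 reversals; discrimination and
identification are 16-trial forced-choice subtests.  TDI = T + D + I,
classified as anosmia (< 16), hyposmia (16-30.3) or normosmia (> 30.3).
"""

from olfbulb import (
    CohortConfig,
    Responder,
    generate_cohort,
    run_threshold_staircase,
    score_cohort,
    score_staircase,
)

# a deterministic responder who detects dilution steps up to 8 oscillates
# at the 8/9 boundary; every reversal lands on 8 or 9
trace = run_threshold_staircase(Responder(threshold_scale=8, spread=0, lapse=0), seed=0)
print(f"reversal values: {trace.reversal_values}  ->  threshold score "
      f"{score_staircase(trace)}")

cohort = generate_cohort(CohortConfig(n_pd=8, n_npod=8, n_control=8,
                                      raster_shape=(260, 340), seed=5))
scores = score_cohort(cohort, seed=5)
summary = scores.groupby("group")[["T", "D", "I", "TDI"]].mean().round(1)
print("\nmean subtest and composite scores per group:")
print(summary.to_string())
print("\nclassification counts:")
print(scores.groupby(["group", "classification"]).size().to_string())
# controls land in the normosmic range, both patient groups hyposmic
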