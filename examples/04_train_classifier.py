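"""Positive and negative classifier controls at desk scale.

Training the CNN on a cohort with the full planted PD-vs-NPOD surround
difference (surround_effect = 1) should beat chance on held-out subjects;
training on a cohort with no difference (surround_effect = 0) should not.
Runs use the scaled-down protocol: 12 + 12 patients, 40 x 40 crops,
15 epochs (a couple of minutes on one CPU).
"""

from olfbulb import classifier_control_run

for effect, label in ((1.0, "positive control (planted signal)"),
                      (0.0, "negative control (no signal)")):
    run = classifier_control_run(surround_effect=effect, seed=1)
    print(f"{label}:")
    print(f"  final training accuracy {run.final_train_accuracy:.3f}")
    print(f"  held-out test accuracy  {run.test_accuracy:.3f} "
          f"({run.n_test_correct}/{run.n_test_scans} scans)")
# test accuracy near 1.0 with the signal, near 0.5 without it: the
# classifier recovers exactly the structure the generator planted
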