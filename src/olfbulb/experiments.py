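"""Desk-scale control experiments for the classification pipeline.

The clinical cohort behind this pipeline is private, so classifier
validity is established by parameter recovery on phantoms instead of by
reproducing a clinical accuracy figure:

* positive control -- cohorts generated with ``surround_effect = 1`` carry
  a real PD-vs-NPOD structural difference above the bulb, and a classifier
  trained on them should beat chance on held-out subjects;
* negative control -- ``surround_effect = 0`` cohorts carry no PD/NPOD
  difference at all, and held-out accuracy should be statistically
  indistinguishable from 0.5.

The scaled-down protocol used here keeps the full architecture and
subject-level splitting but shrinks the problem so a run takes seconds on
one CPU: 12 + 12 patients, 150 px bulb-centred crops downsampled to
40 x 40, 3 augmented copies per training scan, 15 epochs of SGD at
learning rate 0.02 (the clinical-scale rate of 3e-4 pairs with a
100-epoch, ~5000-scan budget and is far too slow at this scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortConfig, generate_cohort
from .cnn import ArchitectureSpec, SmallCNN, TrainConfig, train
from .prep import AugmentConfig, build_dataset, subject_split
from .saliency import SaliencyMap, gradcam


@dataclass
class ControlRun:
    model: SmallCNN
    test_accuracy: float
    n_test_scans: int
    n_test_correct: int
    final_train_accuracy: float
    x_test: np.ndarray
    y_test: np.ndarray
    image_size: int


def classifier_control_run(
    surround_effect: float,
    seed: int,
    n_per_group: int = 12,
    image_size: int = 40,
    n_aug: int = 3,
    epochs: int = 15,
    learning_rate: float = 0.02,
) -> ControlRun:
    """One scaled-down train/test cycle on a freshly generated cohort.

    Generates a patients-only phantom cohort with the given
    ``surround_effect``, splits subjects 3:1:1, trains the CNN on
    augmented 40 x 40 crops and evaluates scan accuracy on the held-out
    test subjects.
    """
    cfg = CohortConfig(n_pd=n_per_group, n_npod=n_per_group, n_control=0,
                       raster_shape=(260, 340), surround_effect=surround_effect,
                       seed=seed)
    cohort = generate_cohort(cfg)
    patients = cohort.subjects_in("PD", "NPOD")
    assignment = subject_split([s.subject_id for s in patients],
                               [s.group for s in patients], seed=seed)
    ds = build_dataset(cohort, assignment, crop_size=150, image_size=image_size,
                       augment_config=AugmentConfig(n_per_scan=n_aug, seed=seed),
                       channels=3)
    x_tr, y_tr, _ = ds["train"]
    x_te, y_te, _ = ds["test"]
    model = SmallCNN(ArchitectureSpec(input_size=(image_size, image_size),
                                      channels=3), seed=seed)
    history = train(model, x_tr, y_tr,
                    TrainConfig(batch_size=32, epochs=epochs,
                                learning_rate=learning_rate, seed=seed))
    _, pred = model.predict(x_te)
    correct = int((pred == y_te).sum())
    return ControlRun(model=model, test_accuracy=correct / len(y_te),
                      n_test_scans=len(y_te), n_test_correct=correct,
                      final_train_accuracy=history.accuracy[-1],
                      x_test=x_te, y_test=np.asarray(y_te),
                      image_size=image_size)


def saliency_maps_for_run(run: ControlRun) -> list[SaliencyMap]:
    """Grad-CAM maps of the correctly classified held-out scans, each
    anchored at the crop centre (crops are bulb-centred)."""
    _, pred = run.model.predict(run.x_test)
    centre = (run.image_size / 2.0, run.image_size / 2.0)
    return [
        gradcam(run.model, run.x_test[i], int(run.y_test[i]), anchor=centre)
        for i in range(len(run.x_test)) if pred[i] == run.y_test[i]
    ]
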