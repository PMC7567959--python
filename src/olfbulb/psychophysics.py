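"""Sniffin' Sticks psychophysics: staircase threshold, discrimination,
identification, composite TDI scoring and normative classification.

The odor threshold test is a single 2-down-1-up staircase over 16 dilution
steps presented in a 3-alternative forced choice (chance 1/3).  The
internal sensitivity scale runs 1-16 with *higher = more dilute detected*,
so a better nose converges higher and the threshold score is simply the
mean of the last four of seven reversal values.  Discrimination and
identification are 16-trial forced-choice subtests modeled as Bernoulli
sums.  The composite TDI = T + D + I (range 1-48) is classified as
functional anosmia (< 16), hyposmia (16 to 30.3) or normosmia (> 30.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .cohort import ResponderTruth

SCALE_MIN, SCALE_MAX = 1, 16
N_REVERSALS = 7
N_SCORED_REVERSALS = 4
CHANCE = 1.0 / 3.0  # 3-alternative forced choice

ANOSMIA, HYPOSMIA, NORMOSMIA = "anosmia", "hyposmia", "normosmia"


@dataclass
class Responder:
    """P(correct | dilution step) of one simulated participant.

    ``p = 1/3 + (2/3)(1 - lapse) * sigmoid((threshold - scale)/spread)``:
    above chance below the subject's threshold step, decaying to guessing
    for more dilute pens.  ``spread -> 0`` gives the deterministic
    responder (correct iff scale <= threshold).
    """

    threshold_scale: float
    spread: float = 0.5
    lapse: float = 0.02

    @classmethod
    def from_truth(cls, truth: ResponderTruth, spread: float = 0.5) -> "Responder":
        return cls(threshold_scale=truth.threshold_scale, spread=spread, lapse=truth.lapse)

    def p_correct(self, scale: int | float) -> float:
        if self.spread == 0:
            detect = 1.0 if scale <= self.threshold_scale else 0.0
        else:
            detect = float(expit((self.threshold_scale - scale) / self.spread))
        return CHANCE + (1.0 - CHANCE) * (1.0 - self.lapse) * detect


@dataclass
class StaircaseTrace:
    trials: list[tuple[int, bool, str]] = field(default_factory=list)  # (scale, correct, event)
    reversal_values: list[int] = field(default_factory=list)
    complete: bool = False

    @property
    def score(self) -> float | None:
        return score_staircase(self) if self.complete else None


@dataclass
class OlfactoryScores:
    threshold: float     # 1-16
    discrimination: int  # 0-16
    identification: int  # 0-16

    def __post_init__(self) -> None:
        if not (SCALE_MIN <= self.threshold <= SCALE_MAX):
            raise ValueError("threshold score out of [1, 16]")
        for name, v in (("discrimination", self.discrimination),
                        ("identification", self.identification)):
            if not (0 <= v <= 16):
                raise ValueError(f"{name} score out of [0, 16]")

    @property
    def tdi(self) -> float:
        return self.threshold + self.discrimination + self.identification

    @property
    def classification(self) -> str:
        if self.tdi < 16:
            return ANOSMIA
        if self.tdi <= 30.3:
            return HYPOSMIA
        return NORMOSMIA


def run_threshold_staircase(
    responder: Responder,
    seed: int | np.random.Generator,
    max_trials: int = 200,
    start_scale: int = SCALE_MIN,
) -> StaircaseTrace:
    """Run the 2-down-1-up threshold staircase.

    One incorrect answer steps toward concentration (scale - 1); two
    consecutive correct answers step toward dilution (scale + 1).  A change
    in step direction records a reversal at the turning-point scale value.
    A step blocked by the scale boundary neither moves nor reverses.
    Terminates at 7 reversals (complete) or ``max_trials`` (incomplete).
    """
    if max_trials < 1:
        raise ValueError("max_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trace = StaircaseTrace()
    scale = int(np.clip(start_scale, SCALE_MIN, SCALE_MAX))
    streak = 0
    last_direction = 0

    for _ in range(max_trials):
        correct = bool(rng.random() < responder.p_correct(scale))
        direction = 0
        if correct:
            streak += 1
            if streak == 2:
                streak = 0
                direction = +1
        else:
            streak = 0
            direction = -1

        event = "step"
        if direction != 0:
            new_scale = int(np.clip(scale + direction, SCALE_MIN, SCALE_MAX))
            if new_scale != scale:  # boundary-blocked moves record nothing
                if last_direction != 0 and direction != last_direction:
                    trace.reversal_values.append(scale)
                    event = "reversal"
                last_direction = direction
                scale = new_scale
        trace.trials.append((scale, correct, event))
        if len(trace.reversal_values) == N_REVERSALS:
            trace.complete = True
            break
    return trace


def score_staircase(trace: StaircaseTrace) -> float:
    """Threshold score = mean of the last 4 of the 7 reversal values."""
    if not trace.complete or len(trace.reversal_values) < N_REVERSALS:
        raise ValueError("staircase incomplete: fewer than 7 reversals")
    last = trace.reversal_values[-N_SCORED_REVERSALS:]
    return float(np.mean(last))


def simulate_subtest(p_success: float, seed: int | np.random.Generator, n_trials: int = 16) -> int:
    """16-trial forced-choice subtest as a Bernoulli sum."""
    if not (0.0 <= p_success <= 1.0):
        raise ValueError("p_success out of [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return int(rng.binomial(n_trials, p_success))


def classify_tdi(threshold: float, discrimination: int, identification: int) -> OlfactoryScores:
    """Validate subtest scores and classify the composite TDI."""
    return OlfactoryScores(threshold=threshold, discrimination=int(discrimination),
                           identification=int(identification))


def score_subject(truth: ResponderTruth, seed: int | np.random.Generator) -> OlfactoryScores:
    """Simulate the full battery for one subject's latent parameters."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trace = run_threshold_staircase(Responder.from_truth(truth), rng)
    t = score_staircase(trace) if trace.complete else float(SCALE_MIN)
    d = simulate_subtest(truth.p_discrimination, rng)
    i = simulate_subtest(truth.p_identification, rng)
    return classify_tdi(t, d, i)


def score_cohort(cohort, seed: int = 0):
    """Scores for every cohort subject; DataFrame (subject_id, group, T, D,
    I, TDI, classification)."""
    import pandas as pd

    root = np.random.SeedSequence(seed)
    rows = []
    for rec, child in zip(cohort.subjects, root.spawn(len(cohort.subjects))):
        scores = score_subject(cohort.behavioral_truth[rec.subject_id],
                               np.random.default_rng(child))
        rows.append({"subject_id": rec.subject_id, "group": rec.group,
                     "T": scores.threshold, "D": scores.discrimination,
                     "I": scores.identification, "TDI": scores.tdi,
                     "classification": scores.classification})
    return pd.DataFrame(rows)
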