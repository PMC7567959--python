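"""Synthetic phantom cohorts for the olfactory-bulb pipeline.

The clinical cohort this package's analysis chain was designed around
(15 Parkinson's-disease patients, 15 patients with non-parkinsonian
olfactory dysfunction, 15 matched controls; coronal T2-like slices at
0.2 x 0.2 mm in-plane resolution and 2 mm slice thickness) is not publicly
available, so every downstream stage is exercised on phantoms generated
here.  A phantom subject carries

* ground-truth left/right bulb volumes drawn from group-specific
  distributions (both patient groups reduced relative to controls, with no
  PD-vs-NPOD volume difference),
* per-slice elliptical bulb cross-sections whose summed planimetric volume
  equals the ground truth exactly,
* a rendered grayscale slice stack in which a bright cortical band sits
  above the paired bulbs, separated by a dark cleft; the width of that
  bulb-cortex gap and the depth of the olfactory sulcus notch carved into
  the cortex are the *surround* features that differ between PD and NPOD
  in proportion to ``surround_effect`` -- this is the planted signal the
  classifier is meant to find, sitting in the region directly above the
  bulb,
* behavioral responder parameters calibrated so that expected Sniffin'
  Sticks scores land in the normosmic range for controls and the hyposmic
  range for both patient groups.

Determinism: one :class:`CohortConfig` seed drives a ``numpy`` SeedSequence
tree; identical configs produce byte-identical cohorts.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

GROUPS = ("PD", "NPOD", "control")

# Behavioral calibration: per-group (mean, sd) of the responder parameters.
# threshold_scale lives on the 1-16 staircase sensitivity scale (higher =
# detects more dilute); discrimination/identification are per-trial success
# probabilities of the 16-trial subtests, expressed through the subtest
# score mean/sd (score = 16 * p).
BEHAVIORAL_CALIBRATION = {
    "control": {"threshold": (10.4, 2.4), "discrimination": (12.6, 1.6), "identification": (13.5, 1.1)},
    "PD": {"threshold": (2.2, 1.5), "discrimination": (8.5, 2.7), "identification": (7.5, 3.5)},
    "NPOD": {"threshold": (3.0, 3.1), "discrimination": (7.2, 3.4), "identification": (7.5, 2.4)},
}

_AGE_CALIBRATION = {"control": (66.3, 6.3), "PD": (66.8, 7.3), "NPOD": (62.8, 9.2)}
_BDI_CALIBRATION = {"control": (1.2, 1.6), "PD": (6.1, 3.4), "NPOD": (2.3, 2.9)}

# Default rendering geometry, in mm unless noted.  The phantom's appearance
# is a design choice (real scan anatomy is richer); what matters for the
# pipeline is that the planted group signal lives ABOVE the bulb.
_BULB_SEPARATION_MM = 8.0          # centre-to-centre left/right
_CORTEX_THICKNESS_MM = 10.0
_BASE_GAP_MM = 0.6                 # bulb-to-cortex cleft, NPOD/control
_GAP_DELTA_MM = 2.0                # extra cleft width for PD at effect=1
_BASE_SULCUS_DEPTH_MM = 3.0        # sulcus notch depth, NPOD/control
_SULCUS_DELTA_MM = 2.0             # PD shallowing at effect=1
_SULCUS_WIDTH_MM = 1.6
_BACKGROUND_INTENSITY = 20.0
_BULB_INTENSITY = 170.0
_CORTEX_INTENSITY = 145.0
_CONTOUR_VERTICES = 48


@dataclass
class CohortConfig:
    """Generation parameters for one phantom cohort.

    ``bulb_volume_means`` are per-group means in mm^3; ``surround_effect``
    in [0, 1] scales the PD-vs-NPOD structural difference above the bulb
    (0 = no planted difference, a negative-control cohort).
    """

    n_pd: int = 15
    n_npod: int = 15
    n_control: int = 15
    slices_per_subject_range: tuple[int, int] = (5, 9)
    bulb_volume_means: dict[str, float] = field(
        default_factory=lambda: {"control": 55.0, "PD": 37.0, "NPOD": 37.0}
    )
    bulb_volume_sd: float = 8.0
    surround_effect: float = 1.0
    noise_sd: float = 6.0
    pixel_spacing: float = 0.2
    slice_thickness: float = 2.0
    raster_shape: tuple[int, int] = (672, 896)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_pd, self.n_npod, self.n_control) < 0:
            raise ValueError("subject counts must be >= 0")
        if self.n_pd + self.n_npod + self.n_control == 0:
            raise ValueError("cohort must contain at least one subject")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel spacing and slice thickness must be > 0")
        if not (0.0 <= self.surround_effect <= 1.0):
            raise ValueError("surround_effect must lie in [0, 1]")
        lo, hi = self.slices_per_subject_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid slices_per_subject_range")
        for g in GROUPS:
            if self.bulb_volume_means.get(g, 0.0) <= 0:
                raise ValueError(f"bulb volume mean for {g} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    sex: str
    moca: int
    bdi: float
    hoehn_yahr: int | None = None
    disease_duration: float | None = None
    ledd_mg: float | None = None
    true_bulb_volume_left: float = 0.0
    true_bulb_volume_right: float = 0.0


@dataclass
class ResponderTruth:
    """Latent psychophysical parameters of one simulated participant."""

    group: str
    threshold_scale: float   # staircase convergence point on the 1-16 scale
    lapse: float             # probability of an attention lapse (guess)
    p_discrimination: float  # per-trial success, 16-trial discrimination
    p_identification: float  # per-trial success, 16-trial identification

    def expected_tdi(self) -> float:
        """Approximate expected composite score (staircase converges near
        ``threshold_scale``; subtests are 16-trial Bernoulli sums)."""
        return self.threshold_scale + 16.0 * (self.p_discrimination + self.p_identification)


@dataclass
class BulbGeometry:
    center: tuple[float, float]       # (row, col) pixels
    semi_axes: tuple[float, float]    # (row semi-axis, col semi-axis) pixels
    intensity: float = _BULB_INTENSITY


@dataclass
class SurroundGeometry:
    """Cortical band + sulcus notches above the bulbs (pixel units)."""

    cortex_bottom_row: float
    cortex_top_row: float
    sulci: list[tuple[float, float, float]]  # (centre col, width, depth below cortex bottom ... upward)
    intensity: float = _CORTEX_INTENSITY


@dataclass
class SliceStack:
    subject_id: str
    slices: list[np.ndarray]
    pixel_spacing: float
    slice_thickness: float
    bulb_centroid_per_slice: list[dict[str, tuple[float, float]] | None]
    first_bulb_slice: int
    last_bulb_slice: int

    def __post_init__(self) -> None:
        shapes = {s.shape for s in self.slices}
        if len(shapes) > 1:
            raise ValueError("all slices in a stack must share dimensions")

    @property
    def bulb_slice_indices(self) -> list[int]:
        return list(range(self.first_bulb_slice, self.last_bulb_slice + 1))


@dataclass
class BulbContour:
    subject_id: str
    side: str                 # "left" | "right"
    slice_index: int
    vertices: np.ndarray      # (n, 2) float, (row, col) pixel coordinates

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("contour needs >= 3 (row, col) vertices")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[SubjectRecord]
    stacks: dict[str, SliceStack]
    contours: dict[str, list[BulbContour]]
    behavioral_truth: dict[str, ResponderTruth]

    def subjects_in(self, *groups: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group in groups]


def _ellipse_polygon(center, semi_axes, n=_CONTOUR_VERTICES):
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = center[0] + semi_axes[0] * np.sin(t)
    c = center[1] + semi_axes[1] * np.cos(t)
    return np.column_stack([r, c])


def _polygon_area_factor(n=_CONTOUR_VERTICES) -> float:
    # shoelace area of a regular inscribed n-gon of an ellipse = f * a * b
    return 0.5 * n * math.sin(2.0 * math.pi / n)


def render_slice(
    shape: tuple[int, int],
    bulbs: list[BulbGeometry],
    surround: SurroundGeometry | None,
    noise_sd: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Render one coronal phantom slice to an 8-bit grayscale raster.

    Bulbs are bright ellipses on a dark background (T2-like appearance);
    the surround, when given, is a bright cortical band above them with
    dark sulcal notches carved up from its lower edge.  Deterministic for
    a fixed seed.
    """
    h, w = shape
    for b in bulbs:
        r0, c0 = b.center
        ar, ac = b.semi_axes
        if not (0 <= r0 - ar and r0 + ar < h and 0 <= c0 - ac and c0 + ac < w):
            raise ValueError("bulb geometry outside raster bounds")
    if surround is not None and not (0 <= surround.cortex_top_row <= surround.cortex_bottom_row < h):
        raise ValueError("surround geometry outside raster bounds")

    img = np.full(shape, _BACKGROUND_INTENSITY, dtype=float)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]

    if surround is not None:
        band = (rows >= surround.cortex_top_row) & (rows <= surround.cortex_bottom_row)
        img[np.broadcast_to(band, shape)] = surround.intensity
        for s_col, s_width, s_depth in surround.sulci:
            notch = (
                (np.abs(cols - s_col) <= s_width / 2.0)
                & (rows <= surround.cortex_bottom_row)
                & (rows > surround.cortex_bottom_row - s_depth)
            )
            img[notch] = _BACKGROUND_INTENSITY

    for b in bulbs:
        r0, c0 = b.center
        ar, ac = b.semi_axes
        mask = ((rows - r0) / ar) ** 2 + ((cols - c0) / ac) ** 2 <= 1.0
        img[mask] = b.intensity

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def sample_behavioral_truth(group: str, seed: int | np.random.Generator) -> ResponderTruth:
    """Draw latent responder parameters for one subject of ``group``.

    Calibrated so group expectations match the normative picture: controls
    normosmic (expected composite score well above 30.3), both patient
    groups hyposmic (composite near 17-18).
    """
    if group not in BEHAVIORAL_CALIBRATION:
        raise ValueError(f"unknown group {group!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cal = BEHAVIORAL_CALIBRATION[group]
    t = float(np.clip(rng.normal(*cal["threshold"]), 1.0, 16.0))
    p_d = float(np.clip(rng.normal(*cal["discrimination"]) / 16.0, 1.0 / 3.0, 1.0))
    p_i = float(np.clip(rng.normal(*cal["identification"]) / 16.0, 0.25, 1.0))
    return ResponderTruth(group=group, threshold_scale=t, lapse=0.02,
                          p_discrimination=p_d, p_identification=p_i)


def group_expected_tdi(group: str) -> float:
    """Population-level expected composite score under the calibration."""
    if group not in BEHAVIORAL_CALIBRATION:
        raise ValueError(f"unknown group {group!r}")
    cal = BEHAVIORAL_CALIBRATION[group]
    return cal["threshold"][0] + cal["discrimination"][0] + cal["identification"][0]


def _slice_area_weights(n: int) -> np.ndarray:
    # bell-like anterior->posterior profile with an abrupt posterior
    # drop-off (the bulb narrows suddenly into the olfactory tract)
    x = np.linspace(-1.0, 1.0, n)
    w = 1.0 - 0.55 * x**2
    w[-1] *= 0.55
    return w / w.sum()


def _subject_slices(
    sid: str,
    group: str,
    vol_left: float,
    vol_right: float,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> tuple[SliceStack, list[BulbContour]]:
    h, w = cfg.raster_shape
    lo, hi = cfg.slices_per_subject_range
    n_bulb = int(rng.integers(lo, hi + 1))
    px = cfg.pixel_spacing

    # subject-level placement (pixels)
    center_row = h * 0.55 + rng.normal(0.0, 4.0)
    mid_col = w * 0.5 + rng.normal(0.0, 6.0)
    sep_px = (_BULB_SEPARATION_MM + rng.normal(0.0, 0.4)) / px

    # surround: the planted PD-vs-NPOD signal
    effect = cfg.surround_effect if group == "PD" else 0.0
    gap_mm = max(0.2, _BASE_GAP_MM + effect * _GAP_DELTA_MM + rng.normal(0.0, 0.15))
    sulcus_depth_mm = max(0.4, _BASE_SULCUS_DEPTH_MM - effect * _SULCUS_DELTA_MM + rng.normal(0.0, 0.2))

    weights = _slice_area_weights(n_bulb)
    # per-slice target polygon areas (mm^2) per side; planimetric sum * t = V
    areas = {"left": vol_left / cfg.slice_thickness * weights,
             "right": vol_right / cfg.slice_thickness * weights}
    f = _polygon_area_factor()
    aspect = 0.85  # row semi-axis / col semi-axis

    slices: list[np.ndarray] = []
    centroids: list[dict[str, tuple[float, float]] | None] = []
    contours: list[BulbContour] = []

    n_total = n_bulb + 2  # one empty slice before and after the bulb
    for k in range(n_total):
        if k == 0 or k == n_total - 1:
            slices.append(render_slice((h, w), [], None, cfg.noise_sd, rng))
            centroids.append(None)
            continue
        i = k - 1
        bulbs, cents = [], {}
        for side, sign in (("left", -1.0), ("right", 1.0)):
            area_px = areas[side][i] / px**2
            ab = area_px / f
            b_ax = math.sqrt(ab / aspect)
            a_ax = aspect * b_ax
            center = (center_row + rng.normal(0.0, 0.6),
                      mid_col + sign * sep_px / 2.0 + rng.normal(0.0, 0.6))
            bulbs.append(BulbGeometry(center=center, semi_axes=(a_ax, b_ax)))
            cents[side] = center
            contours.append(BulbContour(subject_id=sid, side=side, slice_index=k,
                                        vertices=_ellipse_polygon(center, (a_ax, b_ax))))
        bulb_top = min(b.center[0] - b.semi_axes[0] for b in bulbs)
        cortex_bottom = bulb_top - gap_mm / px
        surround = SurroundGeometry(
            cortex_bottom_row=cortex_bottom,
            cortex_top_row=max(0.0, cortex_bottom - _CORTEX_THICKNESS_MM / px),
            sulci=[(b.center[1], _SULCUS_WIDTH_MM / px, sulcus_depth_mm / px) for b in bulbs],
        )
        slices.append(render_slice((h, w), bulbs, surround, cfg.noise_sd, rng))
        centroids.append(cents)

    stack = SliceStack(
        subject_id=sid, slices=slices, pixel_spacing=px,
        slice_thickness=cfg.slice_thickness, bulb_centroid_per_slice=centroids,
        first_bulb_slice=1, last_bulb_slice=n_bulb,
    )
    return stack, contours


def _subject_record(sid: str, group: str, rng: np.random.Generator,
                    vol_l: float, vol_r: float) -> SubjectRecord:
    age = float(np.clip(rng.normal(*_AGE_CALIBRATION[group]), 40.0, 90.0))
    sex = "F" if rng.random() < (7 / 15 if group != "NPOD" else 6 / 15) else "M"
    rec = SubjectRecord(
        subject_id=sid, group=group, age=round(age, 1), sex=sex,
        moca=int(np.clip(round(rng.normal(27.2, 2.5)), 0, 30)),
        bdi=float(np.clip(round(rng.normal(*_BDI_CALIBRATION[group]), 1), 0.0, 63.0)),
        true_bulb_volume_left=vol_l, true_bulb_volume_right=vol_r,
    )
    if group == "PD":
        rec.hoehn_yahr = int(np.clip(round(rng.normal(1.6, 0.6)), 1, 5))
        rec.disease_duration = float(np.clip(round(rng.normal(6.3, 2.8), 1), 0.5, 30.0))
        rec.ledd_mg = float(np.clip(round(rng.normal(527.0, 211.5), 0), 50.0, 2000.0))
    return rec


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full phantom cohort (records, stacks, ground-truth
    contours, behavioral truth) from one validated config."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    plan = [("PD", config.n_pd), ("NPOD", config.n_npod), ("control", config.n_control)]
    n_subjects = sum(n for _, n in plan)
    child_seeds = root.spawn(n_subjects)

    subjects, stacks, contours, truth = [], {}, {}, {}
    idx = 0
    for group, n in plan:
        for j in range(n):
            sid = f"{group.lower()}{j + 1:02d}"
            rng = np.random.default_rng(child_seeds[idx])
            idx += 1
            mean = config.bulb_volume_means[group]
            vol_l = float(max(5.0, rng.normal(mean, config.bulb_volume_sd)))
            vol_r = float(max(5.0, rng.normal(mean, config.bulb_volume_sd)))
            subjects.append(_subject_record(sid, group, rng, round(vol_l, 2), round(vol_r, 2)))
            stack, subj_contours = _subject_slices(sid, group, round(vol_l, 2), round(vol_r, 2), config, rng)
            stacks[sid] = stack
            contours[sid] = subj_contours
            truth[sid] = sample_behavioral_truth(group, rng)
    return Cohort(config=config, subjects=subjects, stacks=stacks,
                  contours=contours, behavioral_truth=truth)


def scan_anchor(stack: SliceStack, slice_index: int) -> tuple[float, float]:
    """Bulb anchor of one scan: midpoint of the two bulb centroids."""
    cents = stack.bulb_centroid_per_slice[slice_index]
    if cents is None:
        raise ValueError(f"slice {slice_index} contains no bulb")
    (rl, cl), (rr, cr) = cents["left"], cents["right"]
    return ((rl + rr) / 2.0, (cl + cr) / 2.0)


def scan_table(cohort: Cohort, groups: tuple[str, ...] = ("PD", "NPOD")):
    """One row per bulb-containing scan: subject, group, slice, anchor."""
    import pandas as pd

    rows = []
    for rec in cohort.subjects_in(*groups):
        stack = cohort.stacks[rec.subject_id]
        for k in stack.bulb_slice_indices:
            ar, ac = scan_anchor(stack, k)
            rows.append({"subject_id": rec.subject_id, "group": rec.group,
                         "slice_index": k, "anchor_row": ar, "anchor_col": ac})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization: PNG per slice, JSON sidecar per subject, cohort-level CSV

def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "subjects").mkdir(parents=True, exist_ok=True)

    with open(out / "cohort.csv", "w", newline="") as fh:
        fields = list(asdict(cohort.subjects[0]).keys())
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for rec in cohort.subjects:
            writer.writerow(asdict(rec))

    for sid, stack in cohort.stacks.items():
        for k, img in enumerate(stack.slices):
            Image.fromarray(img, mode="L").save(out / "images" / f"{sid}_s{k:02d}.png")
        sidecar = {
            "subject_id": sid,
            "pixel_spacing": stack.pixel_spacing,
            "slice_thickness": stack.slice_thickness,
            "first_bulb_slice": stack.first_bulb_slice,
            "last_bulb_slice": stack.last_bulb_slice,
            "n_slices": len(stack.slices),
            "centroids": [
                None if c is None else {s: list(map(float, rc)) for s, rc in c.items()}
                for c in stack.bulb_centroid_per_slice
            ],
            "contours": [
                {"side": c.side, "slice_index": c.slice_index,
                 "vertices": c.vertices.tolist()}
                for c in cohort.contours[sid]
            ],
            "behavioral_truth": asdict(cohort.behavioral_truth[sid]),
        }
        with open(out / "subjects" / f"{sid}.json", "w") as fh:
            json.dump(sidecar, fh)
    return out


def read_contours(cohort_dir: str | Path) -> dict[str, list[BulbContour]]:
    """Load per-subject contours from a written cohort directory."""
    out: dict[str, list[BulbContour]] = {}
    for path in sorted(Path(cohort_dir).glob("subjects/*.json")):
        with open(path) as fh:
            sidecar = json.load(fh)
        sid = sidecar["subject_id"]
        out[sid] = [
            BulbContour(subject_id=sid, side=c["side"], slice_index=c["slice_index"],
                        vertices=np.asarray(c["vertices"]))
            for c in sidecar["contours"]
        ]
    return out
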