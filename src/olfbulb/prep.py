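"""Image preparation: bulb-centred cropping, augmentation, subject-level
splitting.

The classification pipeline crops each 672 x 896 coronal slice to a
150 x 150 window centred on the olfactory bulb (so the crop contains the
bulb and its surround), expands every crop into 25 randomly augmented
copies (rotation up to 5 degrees, width/height shifts up to 5%, shear up to
0.05, horizontal flip, intensity rescaling), and partitions subjects --
never scans -- into train/validation/test at a 3:1:1 ratio stratified by
group, so all scans and augmented copies of one subject land in exactly
one partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp, resize

CROP_SIZE = 150
PARTITIONS = ("train", "validation", "test")


@dataclass
class AugmentConfig:
    n_per_scan: int = 25
    rotation_max_deg: float = 5.0
    width_shift_max: float = 0.05   # fraction of width
    height_shift_max: float = 0.05  # fraction of height
    shear_intensity: float = 0.05   # shear angle bound, radians
    horizontal_flip: bool = True
    rescale: float = 1.0 / 255.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_scan < 1:
            raise ValueError("n_per_scan must be >= 1")
        for name in ("rotation_max_deg", "width_shift_max", "height_shift_max",
                     "shear_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rescale <= 0:
            raise ValueError("rescale must be > 0")


def crop_around_bulb(
    image: np.ndarray,
    anchor: tuple[float, float],
    size: int = CROP_SIZE,
) -> np.ndarray:
    """Crop a ``size x size`` window centred on ``anchor`` (row, col).

    Windows overrunning a border are shifted inward rather than padded, so
    the output is always exactly ``size x size`` and contains the anchor.
    """
    h, w = image.shape[:2]
    if h < size or w < size:
        raise ValueError(f"source {h}x{w} smaller than crop {size}x{size}")
    r0 = int(np.clip(round(anchor[0] - size / 2), 0, h - size))
    c0 = int(np.clip(round(anchor[1] - size / 2), 0, w - size))
    return image[r0:r0 + size, c0:c0 + size].copy()


def _sample_transform(shape: tuple[int, int], cfg: AugmentConfig,
                      rng: np.random.Generator) -> tuple[AffineTransform, bool, dict]:
    h, w = shape
    draws = {
        "angle_deg": rng.uniform(-cfg.rotation_max_deg, cfg.rotation_max_deg),
        "shear": rng.uniform(-cfg.shear_intensity, cfg.shear_intensity),
        "shift_rows": rng.uniform(-cfg.height_shift_max, cfg.height_shift_max) * h,
        "shift_cols": rng.uniform(-cfg.width_shift_max, cfg.width_shift_max) * w,
    }
    flip = bool(cfg.horizontal_flip and rng.random() < 0.5)
    # rotate/shear about the image centre, then translate
    centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x, y)
    t = (AffineTransform(translation=-centre)
         + AffineTransform(rotation=math.radians(draws["angle_deg"]), shear=draws["shear"])
         + AffineTransform(translation=centre)
         + AffineTransform(translation=(draws["shift_cols"], draws["shift_rows"])))
    return t, flip, draws


def _is_identity(t: AffineTransform) -> bool:
    return np.allclose(t.params, np.eye(3), atol=1e-12)


def augment(image: np.ndarray, config: AugmentConfig,
            rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """Produce exactly ``n_per_scan`` augmented float copies of one crop.

    Geometric resampling is bilinear with nearest-edge fill (no
    zero-intensity border artifacts near the bulb); intensities are then
    rescaled by ``config.rescale``.  Deterministic under a fixed seed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    img = np.asarray(image, dtype=float)
    out = []
    for _ in range(config.n_per_scan):
        t, flip, _ = _sample_transform(img.shape[:2], config, rng)
        aug = img if _is_identity(t) else warp(img, t.inverse, order=1,
                                               mode="edge", preserve_range=True)
        if flip:
            aug = aug[:, ::-1]
        out.append(aug * config.rescale)
    return out


def augment_dataset(
    images: list[np.ndarray],
    labels: list[str],
    config: AugmentConfig,
) -> tuple[list[np.ndarray], list[str]]:
    """Augment a scan list; output count = len(images) * n_per_scan, with
    each copy inheriting its source scan's label."""
    if len(images) != len(labels):
        raise ValueError("images and labels differ in length")
    config.validate()
    rng = np.random.default_rng(config.seed)
    aug_images: list[np.ndarray] = []
    aug_labels: list[str] = []
    for img, lab in zip(images, labels):
        copies = augment(img, config, rng)
        aug_images.extend(copies)
        aug_labels.extend([lab] * len(copies))
    return aug_images, aug_labels


def _largest_remainder(n: int, ratios: tuple[float, ...]) -> list[int]:
    total = sum(ratios)
    quotas = [n * r / total for r in ratios]
    counts = [int(math.floor(q)) for q in quotas]
    rem = n - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def subject_split(
    subject_ids: list[str],
    groups: list[str],
    ratios: tuple[float, float, float] = (3, 1, 1),
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Stratified subject-level 3:1:1 partition (train/validation/test).

    Each group's subjects are shuffled and allocated by largest-remainder
    rounding of the ratios, so balanced 15 + 15 cohorts yield the canonical
    18/6/6 split with 9/3/3 per group.  Every subject lands in exactly one
    partition; scan-level leakage is impossible by construction.
    """
    if len(subject_ids) != len(groups):
        raise ValueError("subject_ids and groups differ in length")
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids")
    if len(ratios) != 3 or any(r < 0 for r in ratios) or sum(ratios) == 0:
        raise ValueError("ratios must be three nonnegative numbers, not all zero")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_parts = sum(1 for r in ratios if r > 0)
    assignment: dict[str, str] = {}
    for g in sorted(set(groups)):
        members = [s for s, gg in zip(subject_ids, groups) if gg == g]
        if len(members) < n_parts:
            raise ValueError(f"group {g!r} has fewer subjects than partitions")
        members = list(rng.permutation(members))
        counts = _largest_remainder(len(members), tuple(ratios))
        start = 0
        for part, cnt in zip(PARTITIONS, counts):
            for sid in members[start:start + cnt]:
                assignment[sid] = part
            start += cnt
    return assignment


def downsample(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear downsampling of a square crop (used by the scaled-down
    training protocol)."""
    return resize(np.asarray(image, dtype=float), (size, size),
                  order=1, mode="edge", anti_aliasing=True, preserve_range=True)


def build_dataset(
    cohort,
    assignment: dict[str, str],
    crop_size: int = CROP_SIZE,
    image_size: int | None = None,
    augment_config: AugmentConfig | None = None,
    channels: int = 3,
):
    """Assemble per-partition arrays from a cohort's patient scans.

    Crops every bulb-containing PD/NPOD scan around its bulb anchor,
    optionally downsamples to ``image_size``, and augments the training
    partition only (validation/test stay un-augmented originals, rescaled
    to [0, 1]).  Grayscale crops are replicated across ``channels``.
    Returns ``{partition: (X, y, subject_ids)}`` with X of shape
    (n, H, W, C) and y in {0 = NPOD, 1 = PD}.
    """
    from .cohort import scan_anchor

    rescale = 1.0 / 255.0
    data: dict[str, list] = {p: [[], [], []] for p in PARTITIONS}
    rng = (np.random.default_rng(augment_config.seed)
           if augment_config is not None else None)

    for rec in cohort.subjects_in("PD", "NPOD"):
        part = assignment.get(rec.subject_id)
        if part is None:
            continue
        stack = cohort.stacks[rec.subject_id]
        label = 1 if rec.group == "PD" else 0
        for k in stack.bulb_slice_indices:
            crop = crop_around_bulb(stack.slices[k], scan_anchor(stack, k), crop_size)
            if image_size is not None and image_size != crop_size:
                crop = downsample(crop, image_size)
            if part == "train" and augment_config is not None:
                copies = augment(crop, augment_config, rng)
            else:
                copies = [np.asarray(crop, dtype=float) * rescale]
            for c in copies:
                data[part][0].append(np.repeat(c[:, :, None], channels, axis=2))
                data[part][1].append(label)
                data[part][2].append(rec.subject_id)

    out = {}
    for part, (xs, ys, sids) in data.items():
        if xs:
            out[part] = (np.stack(xs).astype(np.float32), np.asarray(ys), list(sids))
        else:
            out[part] = (np.zeros((0, 0, 0, channels), dtype=np.float32), np.asarray([], dtype=int), [])
    return out
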