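"""Grad-CAM saliency for the scan classifier, and group-level averaging.

Grad-CAM for a class c: take the gradient of the class logit with respect
to the last convolution layer's activations, average it spatially per
channel to get channel weights, form the rectified weighted sum of the
activation channels, upsample bilinearly to the input size, and normalise
the map to max 1 (an all-zero map stays zero).

Group maps: saliency maps of correctly classified scans are translated so
their per-scan bulb anchors coincide, averaged pixelwise over the valid
overlap, and thresholded at a quantile of the mean map to extract the
class-discriminative region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .cnn import SmallCNN


@dataclass
class SaliencyMap:
    relevance: np.ndarray            # nonnegative, max 1 unless the map is null
    class_index: int
    scan_id: str | None = None
    anchor: tuple[float, float] | None = None


@dataclass
class GroupSaliency:
    mean: np.ndarray                 # pixelwise mean over aligned maps
    mask: np.ndarray                 # boolean discriminative-region mask
    n_maps: int
    reference_anchor: tuple[float, float]
    offsets: list[tuple[int, int]]   # integer (row, col) shift applied per map


def gradcam(model: SmallCNN, scan: np.ndarray, class_index: int,
            scan_id: str | None = None,
            anchor: tuple[float, float] | None = None) -> SaliencyMap:
    """Grad-CAM map of one scan for ``class_index``, at input resolution."""
    grad, act, _ = model.grad_wrt_last_conv(scan, class_index)
    weights = grad[0].mean(axis=(0, 1))            # (channels,)
    cam = np.maximum((act[0] * weights).sum(axis=-1), 0.0)
    cam = resize(cam, model.spec.input_size, order=1, mode="edge",
                 preserve_range=True, anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    m = cam.max()
    if m > 0:
        cam = cam / m
    return SaliencyMap(relevance=cam, class_index=class_index,
                       scan_id=scan_id, anchor=anchor)


def average_saliency(maps: list[SaliencyMap],
                     threshold_quantile: float = 0.8) -> GroupSaliency:
    """Align maps on their bulb anchors, average, and threshold.

    Every map needs an anchor.  Maps are shifted by integer offsets so all
    anchors land on the rounded mean anchor; the mean is taken over the
    pixels covered by each shifted map (valid overlap), and the
    discriminative mask keeps pixels at or above the given quantile of the
    covered mean map.
    """
    if not maps:
        raise ValueError("empty map list")
    if any(m.anchor is None for m in maps):
        raise ValueError("every map needs a bulb anchor for alignment")
    if not (0.0 < threshold_quantile < 1.0):
        raise ValueError("threshold_quantile must be in (0, 1)")
    shape = maps[0].relevance.shape
    ref = tuple(np.mean([m.anchor[i] for m in maps]) for i in (0, 1))

    total = np.zeros(shape)
    count = np.zeros(shape)
    offsets = []
    for m in maps:
        dr = int(round(ref[0] - m.anchor[0]))
        dc = int(round(ref[1] - m.anchor[1]))
        offsets.append((dr, dc))
        src_r = slice(max(0, -dr), min(shape[0], shape[0] - dr))
        src_c = slice(max(0, -dc), min(shape[1], shape[1] - dc))
        dst_r = slice(src_r.start + dr, src_r.stop + dr)
        dst_c = slice(src_c.start + dc, src_c.stop + dc)
        total[dst_r, dst_c] += m.relevance[src_r, src_c]
        count[dst_r, dst_c] += 1.0
    covered = count > 0
    mean = np.zeros(shape)
    mean[covered] = total[covered] / count[covered]
    thresh = np.quantile(mean[covered], threshold_quantile)
    mask = covered & (mean >= thresh)
    return GroupSaliency(mean=mean, mask=mask, n_maps=len(maps),
                         reference_anchor=ref, offsets=offsets)


def mask_center_of_mass(group: GroupSaliency) -> tuple[float, float]:
    """Relevance-weighted centroid of the discriminative mask (row, col)."""
    rows, cols = np.nonzero(group.mask)
    if len(rows) == 0:
        raise ValueError("empty discriminative mask")
    w = group.mean[rows, cols]
    return float(np.average(rows, weights=w)), float(np.average(cols, weights=w))
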