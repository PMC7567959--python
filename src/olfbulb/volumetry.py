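"""Planimetric olfactory-bulb volumetry.

Volume of one bulb = slice thickness x sum of manually contoured
cross-sectional areas over the consecutive slices on which the bulb is
visible (from the first anterior slice where it appears to the slice
before the abrupt diameter drop marking the olfactory tract).  Areas are
computed with the shoelace formula on the contour polygon in pixel
coordinates, scaled by the squared pixel spacing.

Also implements the measurement-reliability protocol used for manual
contouring: every volume is measured twice; if the two measurements agree
to within 10% of their average their mean is used, otherwise a third
measurement is taken and the two closest of the three are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LinearRing

from .cohort import BulbContour, Cohort

#: outcome of the two/three-measurement combination rule
STATUS_AGREED = "two_measurements"
STATUS_THIRD_USED = "third_measurement_used"


class NeedsThirdMeasurement(ValueError):
    """The first two measurements disagree by more than 10% of their
    average and no third measurement was supplied."""


@dataclass
class VolumeMeasurement:
    subject_id: str
    side: str
    volume: float              # mm^3
    measurement_index: int = 1


def polygon_area(contour: BulbContour, pixel_spacing: float) -> float:
    """Shoelace area of a closed contour polygon, in mm^2.

    Orientation- and starting-vertex-independent.  Self-intersecting
    polygons are rejected.
    """
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be > 0")
    v = contour.vertices
    if len(v) < 3:
        raise ValueError("polygon needs >= 3 vertices")
    if not LinearRing(v).is_simple:
        raise ValueError("polygon is self-intersecting")
    r, c = v[:, 0], v[:, 1]
    shoelace = 0.5 * np.abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))
    return float(shoelace) * pixel_spacing**2


def bulb_volume(
    contours: list[BulbContour],
    slice_thickness: float,
    pixel_spacing: float,
    slice_range: tuple[int, int] | None = None,
) -> float:
    """Planimetric volume (mm^3) of one subject-side from its contours.

    ``slice_range`` (first, last), when given, restricts the summation to
    the inclusive window of slices on which the bulb counts as visible.
    """
    if not contours:
        raise ValueError("empty contour list")
    keys = {(c.subject_id, c.side) for c in contours}
    if len(keys) > 1:
        raise ValueError(f"contours mix subject-sides: {sorted(keys)}")
    if slice_range is not None:
        lo, hi = slice_range
        contours = [c for c in contours if lo <= c.slice_index <= hi]
        if not contours:
            raise ValueError("no contours within slice_range")
    indices = [c.slice_index for c in contours]
    if len(indices) != len(set(indices)):
        raise ValueError("duplicate slice index in contour list")
    total_area = sum(polygon_area(c, pixel_spacing) for c in contours)
    return slice_thickness * total_area


def combine_measurements(
    m1: float, m2: float, m3: float | None = None
) -> tuple[float, str]:
    """Apply the 10% repeated-measurement rule.

    Returns ``(final volume, status)``.  When the first two measurements
    differ by more than 10% of their average, a third is required and the
    two closest of the three are averaged (a third measurement exactly
    equidistant from the first two averages all three).
    """
    if m1 <= 0 or m2 <= 0:
        raise ValueError("measurements must be > 0")
    avg = (m1 + m2) / 2.0
    if abs(m1 - m2) <= 0.10 * avg:
        return avg, STATUS_AGREED
    if m3 is None:
        raise NeedsThirdMeasurement(
            f"|{m1} - {m2}| exceeds 10% of their average; third measurement required"
        )
    d12, d13, d23 = abs(m1 - m2), abs(m1 - m3), abs(m2 - m3)
    dmin = min(d12, d13, d23)
    if d13 == d23 and d13 <= d12:
        return (m1 + m2 + m3) / 3.0, STATUS_THIRD_USED  # equidistant tie
    if d12 == dmin:
        pair = (m1, m2)
    elif d13 == dmin:
        pair = (m1, m3)
    else:
        pair = (m2, m3)
    return sum(pair) / 2.0, STATUS_THIRD_USED


def subject_volumes(cohort: Cohort):
    """Volume per subject-side from the cohort's ground-truth contours.

    Returns a DataFrame (subject_id, group, side, volume_mm3, true_volume_mm3).
    """
    import pandas as pd

    rows = []
    for rec in cohort.subjects:
        stack = cohort.stacks[rec.subject_id]
        window = (stack.first_bulb_slice, stack.last_bulb_slice)
        for side, truth in (("left", rec.true_bulb_volume_left),
                            ("right", rec.true_bulb_volume_right)):
            cs = [c for c in cohort.contours[rec.subject_id] if c.side == side]
            vol = bulb_volume(cs, stack.slice_thickness, stack.pixel_spacing,
                              slice_range=window)
            rows.append({"subject_id": rec.subject_id, "group": rec.group,
                         "side": side, "volume_mm3": vol, "true_volume_mm3": truth})
    return pd.DataFrame(rows)
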