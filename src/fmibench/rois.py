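"""Signal/background ROI masks and per-region intensity statistics.

Per well: a signal disk and a concentric background annulus ("b1") whose
outer radius is 40% larger than the well radius; one shared well-sized disk
("b2") far from the wells.  Annulus pixels that fall in any other well's
disk, or that are shared between two annuli, are excluded so that every
background pixel is counted at most once and never overlaps signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, MaskError
from .io import IntensityImage
from .segmentation import WellSet

ANNULUS_FACTOR = 1.4  # b1 outer radius / well radius


@dataclass(frozen=True)
class RoiMaskSet:
    """Boolean masks for the 9 wells, their 9 b1 annuli and the b2 disk."""

    well_masks: tuple  # 9 boolean arrays
    b1_masks: tuple  # 9 boolean arrays
    b2_mask: np.ndarray
    image_shape: tuple[int, int]
    depths_mm: np.ndarray = None
    well_centers: np.ndarray = None
    well_radius: float = 0.0


@dataclass(frozen=True)
class RegionStats:
    """Summary statistics of the intensities under one mask."""

    mean: float
    std: float
    min: float
    max: float
    count: int
    saturated_count: int = 0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise MaskError("RegionStats requires at least one pixel")
        if not (self.min <= self.mean <= self.max and self.std >= 0):
            raise MaskError("inconsistent region statistics")


def _sq_dist(shape, center):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2


def build_masks(wells: WellSet, image_shape: tuple[int, int]) -> RoiMaskSet:
    """Construct the ROI masks for a registered well set.

    Pixel membership uses pixel-center coordinates with an inclusive
    boundary: pixel p is in well i iff |p - ci| <= r, in its annulus iff
    r < |p - ci| <= 1.4 r.
    """
    shape = tuple(image_shape)
    r = wells.radius
    r_out = ANNULUS_FACTOR * r
    for c in wells.centers:
        if (
            c[0] - r_out < -0.5
            or c[1] - r_out < -0.5
            or c[0] + r_out > shape[0] - 0.5
            or c[1] + r_out > shape[1] - 0.5
        ):
            raise GeometryError(f"well at {c} with annulus outside image")
    b2c, b2r = wells.b2_center, wells.b2_radius
    if (
        b2c[0] - b2r < -0.5
        or b2c[1] - b2r < -0.5
        or b2c[0] + b2r > shape[0] - 0.5
        or b2c[1] + b2r > shape[1] - 0.5
    ):
        raise GeometryError("b2 circle outside image")

    d2 = [_sq_dist(shape, c) for c in wells.centers]
    well_masks = [d <= r**2 for d in d2]
    raw_annuli = [(d > r**2) & (d <= r_out**2) for d in d2]
    any_well = np.logical_or.reduce(well_masks)

    b1_masks = []
    for i, ann in enumerate(raw_annuli):
        clipped = ann & ~any_well
        for j, other in enumerate(raw_annuli):
            if j != i:
                clipped = clipped & ~other  # shared annulus pixels drop from both
        b1_masks.append(clipped)

    b2_mask = _sq_dist(shape, b2c) <= b2r**2

    any_b1 = np.logical_or.reduce(b1_masks)
    if np.any(b2_mask & (any_well | any_b1)):
        raise MaskError("b2 mask intersects a well or annulus mask")
    for name, masks in (("well", well_masks), ("b1", b1_masks)):
        for i, m in enumerate(masks):
            if not m.any():
                raise MaskError(f"{name} mask {i} is empty")
    if not b2_mask.any():
        raise MaskError("b2 mask is empty")

    return RoiMaskSet(
        well_masks=tuple(well_masks),
        b1_masks=tuple(b1_masks),
        b2_mask=b2_mask,
        image_shape=shape,
        depths_mm=wells.depths_mm,
        well_centers=wells.centers,
        well_radius=r,
    )


def region_stats(
    image: IntensityImage | np.ndarray,
    mask: np.ndarray,
    ddof: int = 0,
    saturation_value: int | None = None,
) -> RegionStats:
    """Mean/std/min/max/count of the masked pixels.

    ``ddof=0`` (population std) is the default; pass ``ddof=1`` for the
    sample convention.  Saturated pixels are counted, not excluded.
    """
    if isinstance(image, IntensityImage):
        values = image.values
        if saturation_value is None:
            saturation_value = image.saturation_value
    else:
        values = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise GeometryError("mask shape does not match image")
    px = values[mask]
    if px.size == 0:
        raise MaskError("empty mask")
    sat = int(np.count_nonzero(px >= saturation_value)) if saturation_value else 0
    return RegionStats(
        mean=float(px.mean()),
        std=float(px.std(ddof=ddof)),
        min=float(px.min()),
        max=float(px.max()),
        count=int(px.size),
        saturated_count=sat,
    )
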