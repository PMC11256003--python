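"""Well localisation: Otsu binarisation, circular Hough detection and
least-squares registration of the design template.

The registration step is what guarantees that all nine wells enter the
analysis with one common radius at the template layout, even when the
deepest (faintest) wells never pass the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops
from skimage.transform import hough_circle, hough_circle_peaks

from .errors import (
    DegenerateHistogramError,
    GeometryError,
    RegistrationError,
    RegistrationQualityError,
)
from .io import IntensityImage
from .template import PhantomTemplate, SimilarityTransform, apply_transform

N_BINS = 256  # histogram resolution for thresholding, both bit depths


@dataclass(frozen=True)
class DetectedCircle:
    center: tuple[float, float]  # (row, col) px
    radius: float  # px
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise GeometryError(f"circle radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class WellSet:
    """Nine registered wells sharing one radius, in pixel space."""

    centers: np.ndarray  # (9, 2) (row, col) px
    radius: float  # common radius, px
    depths_mm: np.ndarray  # (9,)
    b2_center: np.ndarray  # (2,) px
    b2_radius: float
    transform: SimilarityTransform
    residual_rms: float = 0.0
    n_matched: int = 9

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", centers)
        object.__setattr__(
            self, "depths_mm", np.asarray(self.depths_mm, dtype=float)
        )
        object.__setattr__(
            self, "b2_center", np.asarray(self.b2_center, dtype=float)
        )
        if centers.shape != (9, 2):
            raise GeometryError("WellSet requires exactly 9 wells")
        if not self.radius > 0:
            raise GeometryError("common radius must be > 0")
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        iu = np.triu_indices(9, k=1)
        if not np.all(d[iu] > 2 * self.radius):
            raise GeometryError("registered wells overlap")


def _otsu_scores(hist: np.ndarray) -> np.ndarray:
    """Between-class variance (up to the constant 1/n^2 factor) for every
    candidate split k: classes bins[<=k] vs bins[>k], scored on bin index.

    Uses the cancellation-free form (w0*m1 - w1*m0)^2 / (w0*w1) with exact
    integer-valued float64 cumulative sums, so ties are bit-reproducible.
    """
    hist = hist.astype(float)
    idx = np.arange(hist.size, dtype=float)
    w0 = np.cumsum(hist)[:-1]
    m0 = np.cumsum(hist * idx)[:-1]
    w1 = hist.sum() - w0
    m1 = (hist * idx).sum() - m0
    scores = np.full(hist.size - 1, -np.inf)
    valid = (w0 > 0) & (w1 > 0)
    num = w0 * m1 - w1 * m0
    scores[valid] = num[valid] ** 2 / (w0[valid] * w1[valid])
    return scores


def otsu_threshold(values: np.ndarray, nbins: int = N_BINS) -> float:
    """Otsu's threshold on an ``nbins``-bin histogram of ``values``,
    returned on the raw count scale.

    The threshold maximises the between-class variance; ties are broken
    toward the lowest qualifying threshold.  Pixels strictly above the
    returned value are foreground.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise DegenerateHistogramError("empty input")
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        raise DegenerateHistogramError("constant image has no threshold")
    hist, edges = np.histogram(values, bins=nbins, range=(vmin, vmax))
    scores = _otsu_scores(hist)
    k = int(np.argmax(scores))  # argmax returns the first (lowest) maximiser
    return float(edges[k + 1])


def binarize(image: IntensityImage | np.ndarray) -> np.ndarray:
    """Boolean mask: pixel is foreground iff its intensity exceeds the
    image's Otsu threshold."""
    values = image.values if isinstance(image, IntensityImage) else image
    return np.asarray(values, dtype=float) > otsu_threshold(values)


def estimate_radius_range(
    mask: np.ndarray, n_expected: int = 9, factor: tuple[float, float] = (0.6, 1.4)
) -> tuple[float, float]:
    """Radius search range from the equivalent radii of the largest
    connected components of a binary mask."""
    lab = label(ndimage.binary_fill_holes(mask))
    props = sorted(regionprops(lab), key=lambda p: p.area, reverse=True)
    if not props:
        raise GeometryError("empty mask: cannot estimate well radius")
    # ignore speck components far smaller than the largest well
    areas = [p.area for p in props[:n_expected] if p.area >= 0.2 * props[0].area]
    r = float(np.median([np.sqrt(a / np.pi) for a in areas]))
    return max(factor[0] * r, 1.0), max(factor[1] * r, 2.0)


def find_circles(
    mask: np.ndarray,
    radius_range: tuple[float, float],
    max_circles: int = 18,
) -> list[DetectedCircle]:
    """Circular-Hough detection of filled disks in a binary mask.

    Returns circles sorted by descending accumulator score after
    non-maximum suppression: a circle whose center lies within ``rmin``
    of a stronger circle's center is dropped.  An empty mask yields an
    empty list.
    """
    rmin, rmax = radius_range
    if not (0 < rmin < rmax):
        raise GeometryError(f"invalid radius range ({rmin}, {rmax})")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []

    # clean ragged thresholded masks: interior holes and speckle would
    # flood the Hough accumulator with spurious edges
    mask = ndimage.binary_fill_holes(mask)
    open_r = max(int(round(rmin / 4)), 1)
    rr, cc = np.ogrid[-open_r : open_r + 1, -open_r : open_r + 1]
    mask = ndimage.binary_opening(mask, structure=rr**2 + cc**2 <= open_r**2)
    if not mask.any():
        return []

    # edge image: mask boundary pixels
    edges = mask & ~ndimage.binary_erosion(mask)
    radii = np.arange(max(int(np.floor(rmin)), 1), int(np.ceil(rmax)) + 1)
    hspaces = hough_circle(edges, radii)
    accums, cx, cy, rad = hough_circle_peaks(
        hspaces,
        radii,
        total_num_peaks=max_circles * 3,
        normalize=True,
    )

    order = np.argsort(-np.asarray(accums), kind="stable")
    kept: list[DetectedCircle] = []
    for i in order:
        center = (float(cy[i]), float(cx[i]))
        if any(
            np.hypot(center[0] - c.center[0], center[1] - c.center[1]) < rmin
            for c in kept
        ):
            continue
        kept.append(
            DetectedCircle(center=center, radius=float(rad[i]), score=float(accums[i]))
        )
        if len(kept) >= max_circles:
            break
    return kept


def _fit_similarity(
    src: np.ndarray, dst: np.ndarray, allow_rotation: bool
) -> SimilarityTransform:
    """Least-squares similarity transform mapping src points onto dst."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    src_c = src.mean(axis=0)
    dst_c = dst.mean(axis=0)
    p = src - src_c
    q = dst - dst_c
    var_p = (p**2).sum()
    if var_p == 0:
        raise RegistrationError("degenerate source points")
    if allow_rotation:
        # Umeyama: rotation from the SVD of the cross-covariance
        h = q.T @ p
        u, s, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(u @ vt))
        rot_m = u @ np.diag([1.0, d]) @ vt
        scale = (s * np.array([1.0, d])).sum() / var_p
        rotation = float(np.arctan2(rot_m[1, 0], rot_m[0, 0]))
    else:
        scale = float((p * q).sum() / var_p)
        rotation = 0.0
    if scale <= 0:
        raise RegistrationError(f"fitted non-positive scale {scale}")
    t0 = SimilarityTransform(scale=scale, rotation=rotation)
    translation = dst_c - t0.apply(src_c)
    return SimilarityTransform(
        scale=scale, rotation=rotation, translation=tuple(translation)
    )


def _vote_translation(
    detected: list[DetectedCircle],
    template_centers: np.ndarray,
    scale0: float,
    tol: float,
) -> np.ndarray:
    """Coarse translation by correspondence voting at a fixed scale: true
    pairings produce a cluster of identical candidate translations."""
    det = np.array([c.center for c in detected])
    cands = (det[:, None, :] - scale0 * template_centers[None, :, :]).reshape(-1, 2)
    counts = (
        np.linalg.norm(cands[:, None, :] - cands[None, :, :], axis=-1) <= tol
    ).sum(axis=1)
    best = int(np.argmax(counts))
    support = np.linalg.norm(cands - cands[best], axis=1) <= tol
    return cands[support].mean(axis=0)


def _match(
    detected: list[DetectedCircle],
    predicted: np.ndarray,
    tol: float,
) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbour matching between predicted template centers
    and detections.  Returns (template_index, detection_index) pairs; if two
    detections tie for a template well, the higher-score one wins."""
    det = np.array([c.center for c in detected])
    dist = np.linalg.norm(predicted[:, None, :] - det[None, :, :], axis=-1)
    pairs: list[tuple[int, int]] = []
    for ti in range(predicted.shape[0]):
        order = np.argsort(dist[ti])
        # among detections nearest to this well, prefer higher score
        di = min(
            (j for j in order if dist[ti, j] <= tol),
            key=lambda j: (dist[ti, j], -detected[j].score),
            default=None,
        )
        if di is None:
            continue
        if np.argmin(dist[:, di]) != ti:
            continue  # not mutual
        pairs.append((ti, int(di)))
    return pairs


def register_template(
    circles: list[DetectedCircle],
    template: PhantomTemplate,
    allow_rotation: bool = False,
    max_residual_frac: float = 0.25,
) -> WellSet:
    """Fit the design template onto detected circles and return all nine
    wells at the transformed template geometry with one common radius.

    Requires at least three matched circles; fails if the post-fit RMS
    residual exceeds ``max_residual_frac`` of the well pitch in pixels.
    """
    if len(circles) < 3:
        raise RegistrationError(
            f"need >= 3 detected circles, got {len(circles)}"
        )
    tpl_centers = template.well_centers
    scale0 = float(np.median([c.radius for c in circles])) / template.well_radius
    pitch_px = template.pitch * scale0
    tol = 0.35 * pitch_px

    translation0 = _vote_translation(circles, tpl_centers, scale0, tol)
    predicted = scale0 * tpl_centers + translation0
    pairs = _match(circles, predicted, tol)
    if len(pairs) < 3:
        raise RegistrationError(
            f"only {len(pairs)} circles matched the template (need >= 3)"
        )

    det = np.array([c.center for c in circles])
    for _ in range(2):  # fit, re-match once with the refined transform
        src = tpl_centers[[ti for ti, _ in pairs]]
        dst = det[[di for _, di in pairs]]
        t = _fit_similarity(src, dst, allow_rotation)
        predicted = t.apply(tpl_centers)
        new_pairs = _match(circles, predicted, tol)
        if len(new_pairs) >= 3:
            pairs = new_pairs

    src = tpl_centers[[ti for ti, _ in pairs]]
    dst = det[[di for _, di in pairs]]
    t = _fit_similarity(src, dst, allow_rotation)
    residual = float(
        np.sqrt(((t.apply(src) - dst) ** 2).sum(axis=1).mean())
    )
    pitch_px = template.pitch * t.scale
    if residual > max_residual_frac * pitch_px:
        raise RegistrationQualityError(
            f"registration RMS residual {residual:.2f} px exceeds "
            f"{max_residual_frac:.2f} x pitch ({pitch_px:.2f} px)"
        )

    mapped = apply_transform(template, t)
    return WellSet(
        centers=mapped.well_centers,
        radius=mapped.well_radius,
        depths_mm=mapped.depths_mm,
        b2_center=mapped.b2_center,
        b2_radius=mapped.b2_radius,
        transform=t,
        residual_rms=residual,
        n_matched=len(pairs),
    )


def segment_wells(
    image: IntensityImage,
    template: PhantomTemplate,
    allow_rotation: bool = False,
) -> WellSet:
    """Binarise, detect circles and register the template in one call."""
    mask = binarize(image)
    radius_range = estimate_radius_range(mask)
    circles = find_circles(mask, radius_range)
    return register_template(circles, template, allow_rotation=allow_rotation)
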