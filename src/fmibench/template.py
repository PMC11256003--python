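"""Design-space geometry of the sensitivity-versus-depth well phantom.

A :class:`PhantomTemplate` describes the nine fluorescent wells (equal
radius, increasing burial depth) plus the distant ``b2`` background circle
in arbitrary *design units*.  A fitted :class:`SimilarityTransform` maps the
template into pixel space; only that mapping carries physical pixel units.

Coordinates are ``(row, col)`` pairs throughout, matching numpy indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import ConfigError, GeometryError, InvalidTransformError

#: Burial depths of the nine wells, in mm from the phantom top surface.
DEFAULT_DEPTHS_MM = (0.2, 0.4, 0.6, 0.8, 1.0, 1.33, 1.66, 2.0, 3.0)

#: Minimum clearance (in well radii) between the b2 center and any well
#: center so that b2 can never intersect a 1.4 r background annulus.
_B2_CLEARANCE = 2.4


@dataclass(frozen=True)
class SimilarityTransform:
    """Rotation + isotropic scale + translation in the image plane.

    ``p' = scale * R(rotation) @ p + translation`` with ``p`` a (row, col)
    point.  ``scale`` must be strictly positive.
    """

    scale: float = 1.0
    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise InvalidTransformError(f"scale must be > 0, got {self.scale}")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix.T + np.asarray(self.translation, dtype=float)
        return out if np.asarray(points).ndim == 2 else out[0]

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        c, s = np.cos(-self.rotation), np.sin(-self.rotation)
        r_inv = np.array([[c, -s], [s, c]])
        t = -inv_scale * r_inv @ np.asarray(self.translation, dtype=float)
        return SimilarityTransform(inv_scale, -self.rotation, (t[0], t[1]))


@dataclass(frozen=True)
class PhantomTemplate:
    """Nine-well sensitivity phantom geometry plus the b2 background circle.

    Invariants (checked on construction): exactly nine wells; depths
    strictly increasing and positive; wells pairwise non-overlapping;
    b2 center at least ``2.4 * well_radius`` from every well center.
    """

    well_centers: np.ndarray  # (9, 2) float, (row, col) design units
    well_radius: float
    depths_mm: np.ndarray  # (9,) float, mm
    b2_center: np.ndarray  # (2,) float
    b2_radius: float = field(default=0.0)  # 0 -> defaults to well_radius

    def __post_init__(self) -> None:
        centers = np.asarray(self.well_centers, dtype=float)
        depths = np.asarray(self.depths_mm, dtype=float)
        object.__setattr__(self, "well_centers", centers)
        object.__setattr__(self, "depths_mm", depths)
        object.__setattr__(
            self, "b2_center", np.asarray(self.b2_center, dtype=float)
        )
        if self.b2_radius == 0.0:
            object.__setattr__(self, "b2_radius", float(self.well_radius))
        if centers.shape != (9, 2):
            raise GeometryError(
                f"expected 9 well centers, got shape {centers.shape}"
            )
        if depths.shape != (9,):
            raise GeometryError(f"expected 9 depths, got shape {depths.shape}")
        if not (np.all(np.diff(depths) > 0) and np.all(depths > 0)):
            raise GeometryError("depths must be strictly increasing and > 0")
        if not self.well_radius > 0:
            raise GeometryError("well_radius must be > 0")
        d = np.linalg.norm(
            centers[:, None, :] - centers[None, :, :], axis=-1
        )
        iu = np.triu_indices(9, k=1)
        if not np.all(d[iu] > 2 * self.well_radius):
            raise GeometryError("wells overlap: center distance <= 2r")
        b2d = np.linalg.norm(centers - self.b2_center, axis=1)
        if not np.all(b2d > _B2_CLEARANCE * self.well_radius):
            raise GeometryError(
                "b2 center closer than 2.4 r to a well center"
            )

    @property
    def pitch(self) -> float:
        """Smallest pairwise distance between well centers."""
        d = np.linalg.norm(
            self.well_centers[:, None, :] - self.well_centers[None, :, :],
            axis=-1,
        )
        iu = np.triu_indices(9, k=1)
        return float(d[iu].min())

    def bounding_box(self, annulus_factor: float = 1.4) -> np.ndarray:
        """((row_min, col_min), (row_max, col_max)) enclosing wells with
        their background annuli and the b2 circle."""
        r = annulus_factor * self.well_radius
        lo = np.minimum(
            self.well_centers.min(axis=0) - r,
            self.b2_center - self.b2_radius,
        )
        hi = np.maximum(
            self.well_centers.max(axis=0) + r,
            self.b2_center + self.b2_radius,
        )
        return np.array([lo, hi])


def default_template() -> PhantomTemplate:
    """The bundled design template: a 3x3 grid of unit-pitch wells, row-major
    in order of increasing depth, with b2 two pitches to the right of the
    grid."""
    grid = np.array(
        [(r, c) for r in range(3) for c in range(3)], dtype=float
    )
    return PhantomTemplate(
        well_centers=grid,
        well_radius=0.3,
        depths_mm=np.array(DEFAULT_DEPTHS_MM),
        b2_center=np.array([1.0, 4.0]),
    )


def apply_transform(
    template: PhantomTemplate, t: SimilarityTransform
) -> PhantomTemplate:
    """Map a template through a similarity transform. Depths are carried
    through unchanged; radii scale by ``t.scale``."""
    return replace(
        template,
        well_centers=t.apply(template.well_centers),
        well_radius=template.well_radius * t.scale,
        b2_center=t.apply(template.b2_center),
        b2_radius=template.b2_radius * t.scale,
    )


def fit_to_image(
    template: PhantomTemplate,
    image_shape: tuple[int, int],
    margin_frac: float = 0.06,
) -> SimilarityTransform:
    """Transform placing the template (wells + annuli + b2) inside an image
    of ``image_shape`` with a fractional margin, centered, rotation 0."""
    rows, cols = image_shape
    (lo, hi) = template.bounding_box()
    span = hi - lo
    usable = np.array([rows, cols]) * (1.0 - 2.0 * margin_frac)
    scale = float(np.min(usable / span))
    if scale <= 0:
        raise GeometryError("image too small for template")
    center_px = np.array([rows / 2.0, cols / 2.0])
    center_design = (lo + hi) / 2.0
    t = center_px - scale * center_design
    return SimilarityTransform(scale=scale, translation=(t[0], t[1]))


def load_template(path) -> PhantomTemplate:
    """Read a template from YAML (keys: well_centers, well_radius,
    depths_mm, b2_center, b2_radius)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        return PhantomTemplate(
            well_centers=np.asarray(data["well_centers"], dtype=float),
            well_radius=float(data["well_radius"]),
            depths_mm=np.asarray(data["depths_mm"], dtype=float),
            b2_center=np.asarray(data["b2_center"], dtype=float),
            b2_radius=float(data.get("b2_radius", 0.0)),
        )
    except KeyError as exc:  # pragma: no cover - config error path
        raise ConfigError(f"template YAML missing key: {exc}") from exc


def save_template(template: PhantomTemplate, path) -> None:
    data = {
        "well_centers": template.well_centers.tolist(),
        "well_radius": float(template.well_radius),
        "depths_mm": template.depths_mm.tolist(),
        "b2_center": template.b2_center.tolist(),
        "b2_radius": float(template.b2_radius),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)
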