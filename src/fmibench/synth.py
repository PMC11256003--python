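"""Synthetic well-phantom image generator with known ground truth.

Renders the nine-well sensitivity region as depth-attenuated, blurred disks
over a dim background, adds shot (Poisson) and read (Gaussian) noise, and
quantizes to the camera bit depth.  An effective exponential attenuation
with depth-growing blur stands in for tissue optics; it is enough to
exercise every downstream analysis stage with a known answer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, GeometryError
from .template import (
    PhantomTemplate,
    SimilarityTransform,
    apply_transform,
    fit_to_image,
)

ANNULUS_FACTOR = 1.4  # b1 outer radius = 1.4 * well radius


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic camera + phantom forward model.

    ``peak_amplitude`` is the surface-well peak above background;
    well *i* has noiseless amplitude ``A0 * exp(-attenuation_mu * depth_i)``
    and is blurred with ``sigma = blur_sigma0 + blur_slope * depth_i``.
    ``poisson_gain`` (counts/photon) of 0 disables shot noise;
    ``read_noise_sigma`` of 0 disables read noise.
    """

    image_shape: tuple[int, int] = (256, 256)
    bit_depth: int = 16
    background_level: float = 100.0
    peak_amplitude: float = 10000.0
    attenuation_mu: float = 0.8  # 1/mm
    blur_sigma0: float = 1.0  # px
    blur_slope: float = 0.8  # px/mm
    poisson_gain: float = 1.0  # counts/photon
    read_noise_sigma: float = 2.0  # counts
    seed: int = 0
    # provenance of the preset's resolution relative to the real sensor
    source_resolution: tuple[int, int] | None = None
    downscale: int | None = None

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ConfigError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.background_level < 0:
            raise ConfigError("background_level must be >= 0")
        if not self.peak_amplitude > 0:
            raise ConfigError("peak_amplitude must be > 0")
        if self.attenuation_mu < 0:
            raise ConfigError("attenuation_mu must be >= 0")

    @property
    def saturation_value(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows: pixel-space template, noiseless image and
    the per-well noiseless mean intensities (over each well disk)."""

    template_px: PhantomTemplate
    well_means: np.ndarray  # (9,) noiseless mean over each well disk
    noiseless: np.ndarray  # float image, counts
    config: SyntheticConfig = field(repr=False, default=None)


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def render_phantom(
    template: PhantomTemplate, cfg: SyntheticConfig
) -> tuple[np.ndarray, GroundTruth]:
    """Render one noisy, quantized phantom image.

    ``template`` must already be in pixel space and must fit inside
    ``cfg.image_shape`` together with the 1.4 r annuli and the b2 circle.
    Identical ``(template, cfg)`` (the seed lives in ``cfg``) give a
    bit-identical image.
    """
    shape = tuple(cfg.image_shape)
    lo, hi = template.bounding_box(ANNULUS_FACTOR)
    if np.any(lo < 0) or hi[0] > shape[0] or hi[1] > shape[1]:
        raise GeometryError(
            f"template bbox {lo}..{hi} outside image shape {shape}"
        )

    noiseless = np.full(shape, float(cfg.background_level))
    for center, depth in zip(template.well_centers, template.depths_mm):
        amp = cfg.peak_amplitude * np.exp(-cfg.attenuation_mu * depth)
        layer = np.zeros(shape)
        layer[_disk_mask(shape, center, template.well_radius)] = amp
        sigma = cfg.blur_sigma0 + cfg.blur_slope * depth
        if sigma > 0:
            layer = gaussian_filter(layer, sigma=sigma)
        noiseless += layer

    well_means = np.array(
        [
            noiseless[_disk_mask(shape, c, template.well_radius)].mean()
            for c in template.well_centers
        ]
    )

    rng = np.random.default_rng(cfg.seed)
    image = noiseless
    if cfg.poisson_gain > 0:
        photons = np.maximum(image / cfg.poisson_gain, 0.0)
        image = rng.poisson(photons).astype(float) * cfg.poisson_gain
    if cfg.read_noise_sigma > 0:
        image = image + rng.normal(0.0, cfg.read_noise_sigma, size=shape)
    image = np.clip(np.rint(image), 0, cfg.saturation_value).astype(cfg.dtype)

    return image, GroundTruth(
        template_px=template,
        well_means=well_means,
        noiseless=noiseless,
        config=cfg,
    )


def render_default(
    cfg: SyntheticConfig,
    template: PhantomTemplate | None = None,
    margin_frac: float = 0.06,
) -> tuple[np.ndarray, GroundTruth, SimilarityTransform]:
    """Fit the (default) design template into the configured frame and
    render it; returns the transform used."""
    from .template import default_template

    tmpl = template if template is not None else default_template()
    t = fit_to_image(tmpl, cfg.image_shape, margin_frac=margin_frac)
    image, truth = render_phantom(apply_transform(tmpl, t), cfg)
    return image, truth, t


# Sensor bit depth and resolution loosely mirror the six systems studied
# (desk-scale: resolutions divided by `downscale`); exposure and fluence are
# folded into peak_amplitude, which is NOT calibrated to any real device.
def system_presets() -> dict[str, SyntheticConfig]:
    def preset(shape, bits, bg, a0, mu, read, seed, src, down):
        return SyntheticConfig(
            image_shape=shape,
            bit_depth=bits,
            background_level=bg,
            peak_amplitude=a0,
            attenuation_mu=mu,
            blur_sigma0=1.0,
            blur_slope=0.8,
            poisson_gain=1.0,
            read_noise_sigma=read,
            seed=seed,
            source_resolution=src,
            downscale=down,
        )

    return {
        "Mob": preset((306, 408), 8, 20.0, 170.0, 0.9, 1.5, 101, (2448, 3264), 8),
        "NIRF I": preset((150, 200), 16, 300.0, 9000.0, 0.7, 4.0, 102, (1200, 1600), 8),
        "NIRF II": preset((276, 345), 16, 250.0, 20000.0, 0.6, 3.0, 103, (2208, 2758), 8),
        "Solaris": preset((275, 312), 16, 200.0, 15000.0, 0.65, 3.0, 104, (2200, 2500), 8),
        "RawFl": preset((128, 128), 16, 150.0, 12000.0, 0.8, 2.5, 105, (1024, 1024), 8),
        "Hybrid": preset((128, 128), 16, 400.0, 30000.0, 0.5, 6.0, 106, (512, 512), 4),
    }


def write_sidecar(path, truth: GroundTruth) -> None:
    """JSON ground-truth sidecar: pixel-space template, per-well noiseless
    means, and a config echo (noiseless image itself is omitted)."""
    tpl = truth.template_px
    cfg = asdict(truth.config) if truth.config is not None else None
    data = {
        "template_px": {
            "well_centers": tpl.well_centers.tolist(),
            "well_radius": float(tpl.well_radius),
            "depths_mm": tpl.depths_mm.tolist(),
            "b2_center": tpl.b2_center.tolist(),
            "b2_radius": float(tpl.b2_radius),
        },
        "well_means": truth.well_means.tolist(),
        "config": cfg,
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
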