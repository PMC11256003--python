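"""Reading phantom images and dark-frame correction.

All metrics downstream are computed on raw counts; images are never
rescaled on load.  RGB inputs are reduced to a single channel (default:
red, where NIR leakage dominates on consumer sensors).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import FormatError, GeometryError

_RGB_RULES = ("red", "green", "blue", "luminance")


@dataclass(frozen=True)
class IntensityImage:
    """A single-channel image on the raw count scale."""

    values: np.ndarray  # 2-D float64, counts
    bit_depth: int
    source_id: str = ""
    dark_corrected: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise FormatError(f"expected 2-D image, got ndim={v.ndim}")
        if self.bit_depth not in (8, 16):
            raise FormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if np.any(v < 0):
            raise FormatError("negative intensities")
        if not self.dark_corrected and np.any(v > self.saturation_value):
            raise FormatError("values exceed saturation for bit depth")

    @property
    def saturation_value(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _reduce_rgb(arr: np.ndarray, rule: str) -> np.ndarray:
    if rule not in _RGB_RULES:
        raise FormatError(f"unknown RGB rule {rule!r}; expected {_RGB_RULES}")
    if rule == "luminance":
        # ITU-R BT.601 weights on raw counts
        return (
            0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
        )
    return arr[..., _RGB_RULES.index(rule)].astype(float)


def read_image(
    path,
    bit_depth_hint: int | None = None,
    rgb_rule: str = "red",
    source_id: str | None = None,
) -> IntensityImage:
    """Read a TIFF or PNG phantom image as raw counts.

    Bit depth is inferred from the file dtype (uint8 -> 8, uint16 -> 16)
    unless ``bit_depth_hint`` overrides it.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc

    if bit_depth_hint is not None:
        bit_depth = bit_depth_hint
    elif arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise FormatError(
            f"cannot infer bit depth from dtype {arr.dtype}; pass a hint"
        )

    if arr.ndim == 3:
        if arr.shape[-1] in (3, 4):
            arr = _reduce_rgb(arr[..., :3], rgb_rule)
        else:
            raise FormatError(f"unsupported image shape {arr.shape}")
    elif arr.ndim != 2:
        raise FormatError(f"unsupported image shape {arr.shape}")
    return IntensityImage(
        values=np.asarray(arr, dtype=float),
        bit_depth=bit_depth,
        source_id=source_id if source_id is not None else path.name,
    )


def write_image(path, values: np.ndarray, bit_depth: int) -> None:
    """Write an integer image as 8/16-bit grayscale TIFF or PNG."""
    if bit_depth not in (8, 16):
        raise FormatError(f"bit_depth must be 8 or 16, got {bit_depth}")
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    arr = np.asarray(values)
    if np.any(arr < 0) or np.any(arr > 2**bit_depth - 1):
        raise FormatError("values out of range for bit depth")
    arr = arr.astype(dtype)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def subtract_dark(image: IntensityImage, dark: IntensityImage) -> IntensityImage:
    """Per-pixel ``max(image - dark, 0)``; the result is flagged as
    dark-corrected."""
    if image.shape != dark.shape:
        raise GeometryError(
            f"shape mismatch: image {image.shape} vs dark {dark.shape}"
        )
    if image.bit_depth != dark.bit_depth:
        raise GeometryError("bit depth mismatch between image and dark frame")
    return replace(
        image,
        values=np.maximum(image.values - dark.values, 0.0),
        dark_corrected=True,
    )
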