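"""SNR and contrast variants computed from ROI statistics.

Four SNR formula families and two contrast formulas, each background-
referenced one evaluated under both background definitions (the per-well
annulus b1 and the distant disk b2), give seven SNR and four contrast
values per well:

    SNR1            sqrt(n)                 n = mean well counts (photon proxy)
    SNR2{b1,b2}     S / sqrt(S + N)         (or S / (S + N), configurable)
    SNR3{b1,b2}     (S - N) / sigma_S
    SNR4{b1,b2}     (S - N) / sigma_N
    CM{b1,b2}       (Imax - Imin) / (Imax + Imin)
    CW{b1,b2}       (Is - Ib) / Ib

All SNRs are reported in dB with the 20*log10 convention (a twofold
signal-to-noise ratio is ~6 dB).  Linear SNR <= 0 maps to the non-detect
sentinel (-inf dB) instead of a complex or NaN value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, UndefinedNoiseError
from .io import IntensityImage
from .rois import RegionStats, RoiMaskSet, region_stats

#: Sentinel for zero/negative linear SNR: not detectable, -inf dB.
NON_DETECT = float("-inf")

SNR_VARIANTS = ("SNR1", "SNR2b1", "SNR2b2", "SNR3b1", "SNR3b2", "SNR4b1", "SNR4b2")
CONTRAST_VARIANTS = ("CMb1", "CMb2", "CWb1", "CWb2")
ALL_VARIANTS = SNR_VARIANTS + CONTRAST_VARIANTS


@dataclass(frozen=True)
class MetricTable:
    """Per-well values of the 11 metric variants for one imaging system.

    ``df`` is tidy: one row per (well, variant) with columns
    well, depth_mm, variant, family, background, scale, value.
    """

    system_id: str
    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def pivot(self) -> pd.DataFrame:
        """wells x variants matrix."""
        return self.df.pivot(index="well", columns="variant", values="value")[
            list(ALL_VARIANTS)
        ]

    def values_for(self, variant: str) -> np.ndarray:
        sel = self.df[self.df["variant"] == variant].sort_values("well")
        return sel["value"].to_numpy()


def to_db(ratio: float) -> float:
    """Amplitude-convention decibels: 20*log10(ratio).

    Zero maps to the non-detect sentinel; negative ratios are a domain
    error (callers map negative *linear SNRs* to the sentinel themselves).
    """
    if ratio < 0:
        raise DomainError(f"dB undefined for negative ratio {ratio}")
    if ratio == 0:
        return NON_DETECT
    return 20.0 * math.log10(ratio)


def _db_or_sentinel(linear: float) -> float:
    return NON_DETECT if linear <= 0 else to_db(linear)


def snr1(signal: RegionStats) -> float:
    """Shot-noise-limited SNR sqrt(n) in dB, with the mean well intensity in
    counts standing in for the photon count n (no gain calibration)."""
    n = signal.mean
    if n < 0:
        raise DomainError(f"negative mean intensity {n}")
    return _db_or_sentinel(math.sqrt(n))


def snr2(
    signal: RegionStats, background: RegionStats, mode: str = "shot"
) -> float:
    """Signal-plus-background SNR in dB.

    ``mode='shot'`` (default): S / sqrt(S + N), the photon-limited form.
    ``mode='ratio'``: S / (S + N).
    """
    s, n = signal.mean, background.mean
    if s < 0 or n < 0:
        raise DomainError("negative mean intensity")
    if s + n == 0:
        return NON_DETECT
    if mode == "shot":
        linear = s / math.sqrt(s + n)
    elif mode == "ratio":
        linear = s / (s + n)
    else:
        raise DomainError(f"unknown snr2 mode {mode!r}")
    return _db_or_sentinel(linear)


def snr3(signal: RegionStats, background: RegionStats) -> float:
    """Background-subtracted mean over the signal's own std, in dB."""
    if signal.std == 0:
        raise UndefinedNoiseError("signal std is zero")
    return _db_or_sentinel((signal.mean - background.mean) / signal.std)


def snr4(signal: RegionStats, background: RegionStats) -> float:
    """Background-subtracted mean over the background std, in dB."""
    if background.std == 0:
        raise UndefinedNoiseError("background std is zero")
    return _db_or_sentinel((signal.mean - background.mean) / background.std)


def michelson(signal: RegionStats, background: RegionStats) -> float:
    """(Imax - Imin) / (Imax + Imin) with Imax the maximum signal pixel and
    Imin the minimum background pixel."""
    imax, imin = signal.max, background.min
    if imax < 0 or imin < 0:
        raise DomainError("negative intensities")
    if imax + imin == 0:
        return NON_DETECT
    return (imax - imin) / (imax + imin)


def weber(signal: RegionStats, background: RegionStats) -> float:
    """(Is - Ib) / Ib with Is the maximum signal pixel and Ib the minimum
    background pixel."""
    ib = background.min
    if ib == 0:
        raise DomainError("Weber contrast undefined for zero background")
    return (signal.max - ib) / ib


def compute_metric_table(
    image: IntensityImage,
    masks: RoiMaskSet,
    system_id: str,
    snr2_mode: str = "shot",
    std_ddof: int = 0,
) -> MetricTable:
    """Evaluate all 11 variants for each of the 9 wells.

    Per-well b1 statistics come from that well's own annulus; b2 statistics
    are shared.  Variants whose formula is undefined on the data (zero
    noise) are recorded as NaN with a note; non-detects carry the -inf
    sentinel.  Nothing is silently dropped.
    """
    b2_stats = region_stats(image, masks.b2_mask, ddof=std_ddof)
    depths = (
        masks.depths_mm
        if masks.depths_mm is not None
        else np.full(9, np.nan)
    )

    rows = []
    notes = {}

    def emit(well, variant, family, background, scale, fn):
        try:
            value = fn()
        except DomainError as exc:  # undefined noise / zero background
            value = float("nan")
            notes[(well, variant)] = str(exc)
        if value == NON_DETECT:
            notes[(well, variant)] = "non-detect"
        rows.append(
            {
                "well": well,
                "depth_mm": float(depths[well]),
                "variant": variant,
                "family": family,
                "background": background,
                "scale": scale,
                "value": value,
            }
        )

    for i in range(9):
        sig = region_stats(image, masks.well_masks[i], ddof=std_ddof)
        b1 = region_stats(image, masks.b1_masks[i], ddof=std_ddof)
        bgs = {"b1": b1, "b2": b2_stats}
        emit(i, "SNR1", "SNR1", "none", "dB", lambda: snr1(sig))
        for bg_name, bg in bgs.items():
            emit(i, f"SNR2{bg_name}", "SNR2", bg_name, "dB",
                 lambda bg=bg: snr2(sig, bg, mode=snr2_mode))
            emit(i, f"SNR3{bg_name}", "SNR3", bg_name, "dB",
                 lambda bg=bg: snr3(sig, bg))
            emit(i, f"SNR4{bg_name}", "SNR4", bg_name, "dB",
                 lambda bg=bg: snr4(sig, bg))
            emit(i, f"CM{bg_name}", "CM", bg_name, "unitless",
                 lambda bg=bg: michelson(sig, bg))
            emit(i, f"CW{bg_name}", "CW", bg_name, "unitless",
                 lambda bg=bg: weber(sig, bg))

    df = pd.DataFrame(rows)
    df["note"] = [
        notes.get((w, v), "") for w, v in zip(df["well"], df["variant"])
    ]
    provenance = {
        "system_id": system_id,
        "dark_corrected": bool(image.dark_corrected),
        "snr2_mode": snr2_mode,
        "std_convention": "sample" if std_ddof == 1 else "population",
        "db_convention": "20*log10",
        "overlap_policy": "exclusive",
        "snr1_photon_proxy": "mean well counts",
    }
    return MetricTable(system_id=system_id, df=df, provenance=provenance)
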