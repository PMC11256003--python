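"""sMAPE-based benchmarking scores and cross-system ranking.

Each metric variant is compared per well against its detection-limit
reference (the value it takes when the signal is exactly twofold the
noise: ~6 dB for SNR, 1/3 for Michelson, 1 for Weber) via the symmetric
mean absolute percentage error.  One SNR variant plus one contrast variant
combine into a benchmarking (BM) score — the mean of the two sMAPEs —
yielding a 7 x 4 map per system; ranks are assigned per map cell across
systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .metrics import ALL_VARIANTS, CONTRAST_VARIANTS, SNR_VARIANTS, MetricTable


@dataclass(frozen=True)
class ReferenceSet:
    """Detection-limit reference values (signal = 2x noise)."""

    snr_db: float = 6.0
    cm: float = 0.33
    cw: float = 1.0

    def __post_init__(self) -> None:
        if not (self.snr_db > 0 and self.cm > 0 and self.cw > 0):
            raise ConfigError("reference values must be strictly positive")

    def for_variant(self, variant: str) -> float:
        if variant.startswith("SNR"):
            return self.snr_db
        if variant.startswith("CM"):
            return self.cm
        if variant.startswith("CW"):
            return self.cw
        raise ConfigError(f"unknown variant {variant!r}")


@dataclass(frozen=True)
class BmResult:
    """Per-variant sMAPE values and the 7 x 4 BM map for one system."""

    system_id: str
    smape: dict  # variant -> float in [0, 1]
    bm: pd.DataFrame  # index = SNR variants, columns = contrast variants
    n_wells: int = 9
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RankTable:
    """Ranks per (SNR variant, contrast variant) cell across systems.

    ``ranks``: 28-row frame indexed by (snr_variant, contrast_variant) with
    one integer column per system; rank K = best under the higher-is-better
    convention.  ``ties`` lists cells where scores were equal.
    """

    ranks: pd.DataFrame
    higher_is_better: bool
    ties: tuple = ()


def smape(values, reference: float) -> float:
    """Symmetric mean absolute percentage error against one reference:
    (1/n) * sum |Xi - Y| / (|Xi| + |Y|), bounded in [0, 1].

    Non-finite measurements (non-detect sentinels, NaN) enter as Xi = 0,
    the pessimistic worst case; a 0/0 term is defined as 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ConfigError("smape requires at least one value")
    if not reference > 0:
        raise ConfigError(f"reference must be > 0, got {reference}")
    x = np.where(np.isfinite(x), x, 0.0)
    denom = np.abs(x) + abs(reference)
    num = np.abs(x - reference)
    terms = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return float(terms.mean())


def bm_score(smape_snr: float, smape_contrast: float) -> float:
    """BM = mean of the two sMAPEs (sum divided by N = 2 metrics)."""
    for v in (smape_snr, smape_contrast):
        if not 0 <= v <= 1:
            raise ConfigError(f"sMAPE out of [0, 1]: {v}")
    return (smape_snr + smape_contrast) / 2.0


def bm_map(table: MetricTable, refs: ReferenceSet | None = None) -> BmResult:
    """sMAPE per variant over the 9 wells, then the 7 x 4 BM map.

    SNR variants are compared on the dB scale against ``refs.snr_db``.
    """
    refs = refs if refs is not None else ReferenceSet()
    smapes = {
        v: smape(table.values_for(v), refs.for_variant(v))
        for v in ALL_VARIANTS
    }
    grid = pd.DataFrame(
        [
            [bm_score(smapes[s], smapes[c]) for c in CONTRAST_VARIANTS]
            for s in SNR_VARIANTS
        ],
        index=list(SNR_VARIANTS),
        columns=list(CONTRAST_VARIANTS),
    )
    n_wells = int(table.df["well"].nunique())
    return BmResult(
        system_id=table.system_id,
        smape=smapes,
        bm=grid,
        n_wells=n_wells,
        provenance={**table.provenance, "references": vars(refs)},
    )


def rank_systems(
    results: list[BmResult], higher_is_better: bool = True
) -> RankTable:
    """Rank systems within each of the 28 BM map cells.

    Under the default convention the system with the highest BM score in a
    cell gets rank K (best) and the lowest gets rank 1 (worst).  Ties are
    broken by lexicographic system id and flagged.
    """
    if len(results) < 2:
        raise ConfigError("ranking requires at least 2 systems")
    layouts = {tuple(r.bm.index) + tuple(r.bm.columns) for r in results}
    if len(layouts) != 1:
        raise ConfigError("BM maps have mismatched layouts")
    ids = [r.system_id for r in results]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate system ids")

    cells = [(s, c) for s in results[0].bm.index for c in results[0].bm.columns]
    rank_rows = []
    ties = []
    for s, c in cells:
        scores = {r.system_id: float(r.bm.loc[s, c]) for r in results}
        # worst first; lexicographically earlier id loses the tie
        order = sorted(
            scores,
            key=lambda k: (scores[k], k),
            reverse=not higher_is_better,
        )
        ranks = {sys: pos + 1 for pos, sys in enumerate(order)}
        seen = {}
        for sys, sc in scores.items():
            seen.setdefault(sc, []).append(sys)
        for sc, group in seen.items():
            if len(group) > 1:
                ties.append(((s, c), tuple(sorted(group))))
        rank_rows.append({"snr_variant": s, "contrast_variant": c, **ranks})

    frame = pd.DataFrame(rank_rows).set_index(["snr_variant", "contrast_variant"])
    return RankTable(ranks=frame, higher_is_better=higher_is_better, ties=tuple(ties))
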