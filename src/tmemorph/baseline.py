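"""Baseline tumor-microenvironment metrics from tile counts.

Simple comparison-model inputs: the per-compartment tile histogram and
five relative composition metrics commonly used in digital-pathology
scoring —

* TSR  — tumor-stroma ratio: stroma / (tumor + stroma)
* iTR  — intratumoral TIL ratio: iTIL / (tumor + iTIL)
* sTR  — stromal TIL ratio: sTIL / (stroma + sTIL)
* TISR — TIL share of the invasive region:
         (iTIL + sTIL) / (tumor + stroma + iTIL + sTIL)
* LD   — lymphocyte density over informative tissue:
         (iTIL + sTIL) / (grid size − excluded)

All ratios lie in [0, 1]; a zero denominator yields NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ts_image as tsi
from .ts_image import TSImage


@dataclass(frozen=True)
class TileCounts:
    n_tumor: int
    n_stroma: int
    n_necrosis: int
    n_itil: int
    n_stil: int
    n_excluded: int

    @property
    def grid_size(self) -> int:
        return (
            self.n_tumor
            + self.n_stroma
            + self.n_necrosis
            + self.n_itil
            + self.n_stil
            + self.n_excluded
        )


def count_tiles(ts: TSImage) -> TileCounts:
    """Exact label histogram of a TS-image."""
    labels = ts.labels
    return TileCounts(
        n_tumor=int(np.sum(labels == tsi.TUMOR)),
        n_stroma=int(np.sum(labels == tsi.STROMA)),
        n_necrosis=int(np.sum(labels == tsi.NECROSIS)),
        n_itil=int(np.sum(labels == tsi.ITIL)),
        n_stil=int(np.sum(labels == tsi.STIL)),
        n_excluded=int(np.sum(labels == tsi.EXCLUDED)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def relative_metrics(counts: TileCounts) -> dict[str, float]:
    """The five relative TME metrics from a tile histogram."""
    tumor, stroma = counts.n_tumor, counts.n_stroma
    itil, stil = counts.n_itil, counts.n_stil
    tils = itil + stil
    return {
        "tsr": _ratio(stroma, tumor + stroma),
        "itr": _ratio(itil, tumor + itil),
        "str_ratio": _ratio(stil, stroma + stil),
        "tisr": _ratio(tils, tumor + stroma + tils),
        "ld": _ratio(tils, counts.grid_size - counts.n_excluded),
    }


def baseline_table(ts_images: list[TSImage]) -> pd.DataFrame:
    """Raw counts plus relative metrics, one row per patient."""
    rows = []
    for ts in ts_images:
        counts = count_tiles(ts)
        row: dict[str, float] = {
            "n_tumor": counts.n_tumor,
            "n_stroma": counts.n_stroma,
            "n_necrosis": counts.n_necrosis,
            "n_itil": counts.n_itil,
            "n_stil": counts.n_stil,
            "n_excluded": counts.n_excluded,
        }
        row.update(relative_metrics(counts))
        rows.append(pd.Series(row, name=ts.patient_id))
    table = pd.DataFrame(rows)
    table.index.name = "patient_id"
    return table
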