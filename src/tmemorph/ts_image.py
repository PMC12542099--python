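"""Tile-resolution tissue-segmentation images (TS-images).

A TS-image is an integer label grid in which each cell stands for one tile
of the source slide and carries exactly one tumor-microenvironment
compartment code:

====  ==========  =============================================
code  name        meaning
====  ==========  =============================================
0     excluded    non-informative tile (fat, ink, blank, <20% tissue)
1     tumor       tumor epithelium
2     stroma      supportive stromal tissue
3     necrosis    necrotic tissue (detected inside tumor regions)
4     itil        intratumoral tumor-infiltrating lymphocytes
5     stil        stromal tumor-infiltrating lymphocytes
====  ==========  =============================================

Lymphocyte compartments are nested by construction: iTIL cells can only
arise from tiles first classified as tumor, and sTIL cells only from tiles
first classified as stroma.  The full TIL compartment is the union of the
two.

The module also implements the sequential binary classification cascade
that builds a TS-image from tiles using three pluggable binary tile
classifiers (tumor-vs-stroma, necrosis, lymphocyte), mirroring the
T-CNN / N-CNN / L-CNN decomposition used with whole-slide images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
from PIL import Image

# Compartment label codes.
EXCLUDED = 0
TUMOR = 1
STROMA = 2
NECROSIS = 3
ITIL = 4
STIL = 5

LABEL_NAMES: dict[int, str] = {
    EXCLUDED: "excluded",
    TUMOR: "tumor",
    STROMA: "stroma",
    NECROSIS: "necrosis",
    ITIL: "itil",
    STIL: "stil",
}
VALID_CODES = frozenset(LABEL_NAMES)

# Palette used when serializing label grids to indexed PNG.  Colors are
# arbitrary but fixed so files are bit-reproducible.
_PALETTE = {
    EXCLUDED: (255, 255, 255),
    TUMOR: (128, 0, 128),
    STROMA: (255, 182, 193),
    NECROSIS: (128, 128, 128),
    ITIL: (0, 0, 200),
    STIL: (200, 0, 0),
}


@dataclass
class TSImage:
    """Integer label grid over tiles for one patient slide."""

    labels: np.ndarray
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 2:
            raise ValueError("TS-image labels must be a 2-D grid")
        bad = set(np.unique(self.labels)) - VALID_CODES
        if bad:
            raise ValueError(f"unknown label code(s): {sorted(bad)}")

    @property
    def grid_height(self) -> int:
        return int(self.labels.shape[0])

    @property
    def grid_width(self) -> int:
        return int(self.labels.shape[1])

    def mask(self, compartment: str) -> np.ndarray:
        """Binary mask of one compartment ('til' = iTIL ∪ sTIL)."""
        if compartment == "til":
            return tils_union(self)
        for code, name in LABEL_NAMES.items():
            if name == compartment:
                return self.labels == code
        raise KeyError(f"unknown compartment {compartment!r}")

    def __eq__(self, other: object) -> bool:  # noqa: D105
        if not isinstance(other, TSImage):
            return NotImplemented
        return self.patient_id == other.patient_id and np.array_equal(
            self.labels, other.labels
        )


class TileClassifier(Protocol):
    """Binary tile classifier: probability of the positive class."""

    def predict(self, tile: np.ndarray) -> float: ...


def classify_cascade(
    tiles: Mapping[tuple[int, int], np.ndarray],
    grid_shape: tuple[int, int],
    tumor_clf: TileClassifier,
    necrosis_clf: TileClassifier,
    lymphocyte_clf: TileClassifier,
    thresholds: Mapping[str, float] | None = None,
    patient_id: str = "",
) -> TSImage:
    """Build a TS-image from retained tiles via the sequential cascade.

    Parameters
    ----------
    tiles
        Mapping from (row, col) grid position to the RGB tile array.
        Grid positions absent from the mapping (tiles dropped by the
        tissue filter) receive the ``excluded`` code.
    grid_shape
        (height, width) of the tile grid.
    tumor_clf, necrosis_clf, lymphocyte_clf
        Binary classifiers for, respectively, tumor-vs-stroma (positive =
        tumor), necrosis-vs-viable and lymphocyte-vs-none.
    thresholds
        Optional per-step decision cutoffs, keys ``tumor`` / ``necrosis``
        / ``lymphocyte``; default 0.5 each.

    The cascade first splits tumor from stroma; tumor tiles are then
    screened for necrosis (necrotic tiles are terminal, since necrosis
    morphologically mimics intratumoral lymphocytes); finally the
    lymphocyte test relabels tumor tiles as iTIL and stroma tiles as sTIL.
    """
    for name, clf in (
        ("tumor", tumor_clf),
        ("necrosis", necrosis_clf),
        ("lymphocyte", lymphocyte_clf),
    ):
        if clf is None:
            raise ValueError(f"missing {name} classifier")
    thr = {"tumor": 0.5, "necrosis": 0.5, "lymphocyte": 0.5}
    if thresholds:
        thr.update(thresholds)
    for key, value in thr.items():
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"threshold {key}={value} outside [0, 1]")

    labels = np.full(grid_shape, EXCLUDED, dtype=np.int64)
    for (row, col), tile in tiles.items():
        if tumor_clf.predict(tile) >= thr["tumor"]:
            if necrosis_clf.predict(tile) >= thr["necrosis"]:
                labels[row, col] = NECROSIS
            elif lymphocyte_clf.predict(tile) >= thr["lymphocyte"]:
                labels[row, col] = ITIL
            else:
                labels[row, col] = TUMOR
        else:
            if lymphocyte_clf.predict(tile) >= thr["lymphocyte"]:
                labels[row, col] = STIL
            else:
                labels[row, col] = STROMA
    return TSImage(labels=labels, patient_id=patient_id)


def tils_union(ts: TSImage) -> np.ndarray:
    """Binary grid of the full TIL compartment (iTIL ∪ sTIL)."""
    return (ts.labels == ITIL) | (ts.labels == STIL)


def write_ts_image(ts: TSImage, path: str | Path) -> Path:
    """Serialize a TS-image as a palette-indexed PNG plus JSON sidecar."""
    path = Path(path)
    img = Image.fromarray(ts.labels.astype(np.uint8), mode="P")
    palette = bytearray(256 * 3)
    for code, rgb in _PALETTE.items():
        palette[3 * code : 3 * code + 3] = bytes(rgb)
    img.putpalette(bytes(palette))
    img.save(path, format="PNG")
    sidecar = {
        "patient_id": ts.patient_id,
        "grid_height": ts.grid_height,
        "grid_width": ts.grid_width,
    }
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=0) + "\n"
    )
    return path


def read_ts_image(path: str | Path) -> TSImage:
    """Read a TS-image written by :func:`write_ts_image`.

    Raises ``ValueError`` naming any label code outside the vocabulary.
    """
    path = Path(path)
    labels = np.asarray(Image.open(path), dtype=np.int64)
    bad = set(np.unique(labels)) - VALID_CODES
    if bad:
        raise ValueError(f"unknown label code(s) in {path.name}: {sorted(bad)}")
    patient_id = ""
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        patient_id = json.loads(sidecar.read_text()).get("patient_id", "")
    return TSImage(labels=labels, patient_id=patient_id)
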