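"""Connected-component morphometry of TS-image compartments.

Each compartment mask (tumor, stroma, iTIL, sTIL, TIL) is decomposed into
8-connected components at tile resolution, each described by 11 standard
region descriptors.  Three aggregation strategies then summarize a
compartment into exactly 46 features:

* **all-region (AR, 12 features)** — component count plus the mean of
  each descriptor over every component: the global view of the tissue
  architecture;
* **largest-region (LR, 11 features)** — the descriptors of the single
  largest component: the dominant structural pattern;
* **significant-region (SR, 23 features)** — the number of "significant"
  components (area strictly exceeding a fraction, default 5%, of the
  largest component's area) plus the mean and population standard
  deviation of each descriptor over them: local heterogeneity among
  non-trivial regions.

Area-type descriptors are in tile units: one tile is the unit of
analysis, so feature values are independent of the underlying pixel
resolution of the slide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as _sk_label
from skimage.measure import regionprops

from .ts_image import TSImage

#: The 11 base descriptors of one connected component, in canonical order.
DESCRIPTORS: tuple[str, ...] = (
    "area",
    "filled_area",
    "convex_area",
    "major_axis_length",
    "minor_axis_length",
    "eccentricity",
    "euler_number",
    "extent",
    "solidity",
    "perimeter",
    "orientation",
)

# regionprops attribute for each descriptor (modern scikit-image names).
_REGIONPROP_ATTR = {
    "area": "area",
    "filled_area": "area_filled",
    "convex_area": "area_convex",
    "major_axis_length": "axis_major_length",
    "minor_axis_length": "axis_minor_length",
    "eccentricity": "eccentricity",
    "euler_number": "euler_number",
    "extent": "extent",
    "solidity": "solidity",
    "perimeter": "perimeter",
    "orientation": "orientation",
}

COMPARTMENTS: tuple[str, ...] = ("tumor", "stroma", "itil", "stil", "til")

DEFAULT_SR_THRESHOLD = 0.05


@dataclass
class Component:
    """One 8-connected region of a compartment mask."""

    cells: frozenset[tuple[int, int]]
    descriptors: dict[str, float]

    @property
    def area(self) -> float:
        return self.descriptors["area"]


def label_components(mask: np.ndarray) -> list[Component]:
    """Maximal 8-connected components of a binary grid.

    Components are returned in deterministic order, sorted by the
    (min row, min col) of their cells.  An empty mask yields an empty
    list.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    labeled = _sk_label(mask, connectivity=2)
    components = []
    for region in regionprops(labeled):
        cells = frozenset((int(r), int(c)) for r, c in region.coords)
        desc = {
            name: float(getattr(region, attr))
            for name, attr in _REGIONPROP_ATTR.items()
        }
        components.append(Component(cells=cells, descriptors=desc))
    components.sort(
        key=lambda comp: (
            min(r for r, _ in comp.cells),
            min(c for _, c in comp.cells),
        )
    )
    return components


def compute_descriptors(component: Component) -> dict[str, float]:
    """The 11 descriptors of a component, in canonical order.

    Values are taken from the component's regionprops measurement: axis
    lengths and eccentricity come from the moment-equivalent ellipse,
    the Euler number counts components minus holes (8-connected
    foreground, 4-connected holes), extent is area over bounding-box
    area, and solidity area over convex area.
    """
    return {name: component.descriptors[name] for name in DESCRIPTORS}


def significant_components(
    components: list[Component], threshold: float = DEFAULT_SR_THRESHOLD
) -> list[Component]:
    """Components whose area strictly exceeds ``threshold`` x max area.

    The strict inequality means a component at exactly the threshold is
    dropped; the largest component itself always qualifies (for any
    threshold < 1).  An empty input yields an empty list.
    """
    if not components:
        return []
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    max_area = max(c.area for c in components)
    return [c for c in components if c.area > threshold * max_area]


def feature_names(compartment: str) -> list[str]:
    """Canonical 46 feature column names for one compartment.

    Naming scheme: ``<compartment>__<strategy>__<descriptor>[__mean|__std]``
    with the AR/SR counts named ``component_count`` / ``num_significant``.
    """
    names = [f"{compartment}__ar__component_count"]
    names += [f"{compartment}__ar__{d}__mean" for d in DESCRIPTORS]
    names += [f"{compartment}__lr__{d}" for d in DESCRIPTORS]
    names += [f"{compartment}__sr__num_significant"]
    names += [f"{compartment}__sr__{d}__mean" for d in DESCRIPTORS]
    names += [f"{compartment}__sr__{d}__std" for d in DESCRIPTORS]
    return names


def all_feature_names(compartments: tuple[str, ...] = COMPARTMENTS) -> list[str]:
    """Feature columns for all compartments (46 per compartment)."""
    out: list[str] = []
    for comp in compartments:
        out += feature_names(comp)
    return out


def compartment_features(
    mask: np.ndarray, threshold: float = DEFAULT_SR_THRESHOLD
) -> list[float]:
    """46 features for one compartment mask (AR 12 + LR 11 + SR 23).

    An empty compartment has no geometry to summarize: all 46 values are
    the missing sentinel (NaN), to be imputed downstream from training
    medians.
    """
    components = label_components(mask)
    if not components:
        return [np.nan] * 46
    matrix = np.array(
        [[c.descriptors[d] for d in DESCRIPTORS] for c in components], dtype=float
    )
    ar = [float(len(components))] + list(matrix.mean(axis=0))
    largest = components[int(np.argmax(matrix[:, 0]))]
    lr = [largest.descriptors[d] for d in DESCRIPTORS]
    sig = significant_components(components, threshold)
    sig_matrix = np.array(
        [[c.descriptors[d] for d in DESCRIPTORS] for c in sig], dtype=float
    )
    sr = (
        [float(len(sig))]
        + list(sig_matrix.mean(axis=0))
        + list(sig_matrix.std(axis=0, ddof=0))
    )
    return ar + lr + sr


def extract_features(
    ts: TSImage,
    threshold: float = DEFAULT_SR_THRESHOLD,
    compartments: tuple[str, ...] = COMPARTMENTS,
) -> pd.Series:
    """Per-patient morphological feature vector over all compartments.

    Returns a Series of 46 x len(compartments) named features (see
    :func:`feature_names`), indexed in canonical order.
    """
    values: list[float] = []
    for comp in compartments:
        values += compartment_features(ts.mask(comp), threshold)
    return pd.Series(
        values, index=all_feature_names(compartments), name=ts.patient_id
    )


def extract_feature_table(
    ts_images: list[TSImage],
    threshold: float = DEFAULT_SR_THRESHOLD,
    compartments: tuple[str, ...] = COMPARTMENTS,
) -> pd.DataFrame:
    """Patients x features table for a cohort of TS-images."""
    rows = [extract_features(ts, threshold, compartments) for ts in ts_images]
    table = pd.DataFrame(rows)
    table.index.name = "patient_id"
    return table
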