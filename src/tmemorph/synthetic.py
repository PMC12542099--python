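"""Seeded synthetic cohorts of TS-images, clinical covariates and outcomes.

The restricted clinical cohorts behind this kind of study (pre-treatment
core-needle biopsies with pathological-complete-response labels) cannot
be redistributed, so this module generates cohorts with *planted*,
configurable group differences that every downstream stage can be tested
against:

* tile-grid tissue layouts drawn from a thresholded smoothed-noise blob
  process, so compartments have irregular, realistic geometry;
* stromal-TIL morphology carrying the planted signal — patients who will
  achieve pCR receive more and larger sTIL components, with the mean of
  component count and component area shifted by a configurable
  standardized effect size;
* clinical covariates (ER/PR status and percentage, HER2/CEP17 ratio)
  with an optional log-odds shift of PR positivity for the pCR group;
* residual infiltration size (RIS): exactly 0 for pCR patients, and for
  non-pCR patients lognormal with configurable median, negatively
  coupled to the planted sTIL burden.

Everything is reproducible bit-for-bit from ``CohortConfig.seed``.

The module also renders synthetic RGB tiles whose mean red intensity
encodes the tile class, together with rule-based reference classifiers
that invert the encoding — a stand-in for trained tile CNNs that lets
the classification cascade be verified exactly against ground truth.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from . import ts_image as tsi
from .ts_image import TSImage

# Planted sTIL morphology baselines (non-pCR group): component count and
# per-component target area in tiles.  The pCR group's means are shifted
# upward by effect_size standard deviations.
_STIL_COUNT_MEAN = 6.0
_STIL_COUNT_SD = 2.0
_STIL_AREA_MEAN = 7.0
_STIL_AREA_SD = 2.5

# Group-independent nuisance structure.
_ITIL_COUNT_MEAN = 3.0
_NECROSIS_COUNT_MEAN = 2.0

# RIS lognormal spread and coupling of RIS to planted sTIL burden.
_RIS_SIGMA = 0.8
_RIS_COUPLING = 0.3

_ER_POS_RATE = 0.65
_PR_BASE_LOGIT = 0.2  # baseline PR-positivity log-odds (~55%)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror a training cohort of 85 patients with a 42% pCR rate
    and a non-pCR median residual infiltration size of 1.35 cm, on
    48 x 48 tile grids.
    """

    n_patients: int = 85
    pcr_fraction: float = 0.42
    grid_height: int = 48
    grid_width: int = 48
    effect_size: float = 1.5
    clinical_effect: float = 1.0
    seed: int = 0
    ris_scale: float = 1.35
    excluded_fraction: float = 0.10
    tumor_fraction: float = 0.50

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        if not 0.0 <= self.pcr_fraction <= 1.0:
            raise ValueError("pcr_fraction outside [0, 1]")
        if self.grid_height <= 0 or self.grid_width <= 0:
            raise ValueError("grid dimensions must be positive")
        if not 0.0 <= self.excluded_fraction < 1.0:
            raise ValueError("excluded_fraction outside [0, 1)")
        if not 0.0 < self.tumor_fraction < 1.0:
            raise ValueError("tumor_fraction outside (0, 1)")
        if self.ris_scale <= 0:
            raise ValueError("ris_scale must be positive")


@dataclass
class SyntheticPatient:
    """One simulated patient: label grid, clinical covariates, outcome."""

    patient_id: str
    ts_image: TSImage
    er_status: int
    er_percent: float
    pr_status: int
    pr_percent: float
    her2_cep17: float
    pcr: int
    ris: float

    def clinical_row(self) -> dict[str, float]:
        return {
            "patient_id": self.patient_id,
            "er": self.er_status,
            "er_pct": round(self.er_percent, 4),
            "pr": self.pr_status,
            "pr_pct": round(self.pr_percent, 4),
            "her2_cep17": round(self.her2_cep17, 4),
            "pcr": self.pcr,
            "ris_cm": round(self.ris, 4),
        }


def _grow_blob(
    rng: np.random.Generator,
    allowed: np.ndarray,
    target_area: int,
) -> list[tuple[int, int]]:
    """Grow an irregular 8-connected blob of ~target_area cells.

    Starts at a random allowed cell and repeatedly annexes a random
    frontier cell (8-neighborhood, restricted to allowed cells).  Stops
    early if the frontier empties, so the realized area can fall short
    of the target in crowded layouts.
    """
    coords = np.argwhere(allowed)
    if len(coords) == 0:
        return []
    start = tuple(coords[rng.integers(len(coords))])
    cells = {start}
    frontier: list[tuple[int, int]] = []
    in_frontier: set[tuple[int, int]] = set()

    def push_neighbors(cell: tuple[int, int]) -> None:
        r, c = cell
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nr, nc = r + dr, c + dc
                if (
                    0 <= nr < allowed.shape[0]
                    and 0 <= nc < allowed.shape[1]
                    and allowed[nr, nc]
                    and (nr, nc) not in cells
                    and (nr, nc) not in in_frontier
                ):
                    frontier.append((nr, nc))
                    in_frontier.add((nr, nc))

    push_neighbors(start)
    while len(cells) < target_area and frontier:
        idx = int(rng.integers(len(frontier)))
        cell = frontier.pop(idx)
        in_frontier.discard(cell)
        cells.add(cell)
        push_neighbors(cell)
    return sorted(cells)


def _plant_components(
    rng: np.random.Generator,
    labels: np.ndarray,
    host_code: int,
    new_code: int,
    n_components: int,
    area_sampler,
    separate: bool = False,
) -> None:
    """Carve blob components of ``new_code`` out of ``host_code`` cells.

    With ``separate=True`` new components keep a one-cell buffer from
    previously planted cells of the same code, so planted component
    counts survive 8-connected labeling.
    """
    for _ in range(n_components):
        allowed = labels == host_code
        if separate:
            existing = labels == new_code
            if existing.any():
                allowed &= ~binary_dilation(existing, np.ones((3, 3), bool))
        if not allowed.any():
            break
        target = max(1, int(round(area_sampler())))
        for r, c in _grow_blob(rng, allowed, target):
            labels[r, c] = new_code


def _generate_ts_image(
    rng: np.random.Generator, config: CohortConfig, pcr: int, patient_id: str
) -> tuple[TSImage, float, float]:
    """One patient's label grid; returns (TS-image, planted count, area).

    Layout: two smoothed Gaussian noise fields are thresholded at exact
    per-slide quantiles to carve out the excluded region and the
    tumor/stroma split, so marginal class fractions match the configured
    priors up to blob-process rounding.
    """
    shape = (config.grid_height, config.grid_width)
    field_a = gaussian_filter(rng.normal(size=shape), sigma=3.0)
    field_b = gaussian_filter(rng.normal(size=shape), sigma=4.0)

    labels = np.full(shape, tsi.STROMA, dtype=np.int64)
    if config.excluded_fraction > 0:
        cut = np.quantile(field_b, 1.0 - config.excluded_fraction)
        labels[field_b >= cut] = tsi.EXCLUDED
    tissue = labels != tsi.EXCLUDED
    if tissue.any():
        cut = np.quantile(field_a[tissue], 1.0 - config.tumor_fraction)
        labels[tissue & (field_a >= cut)] = tsi.TUMOR

    # Group-independent nuisance: necrosis then iTILs inside tumor.
    n_nec = int(rng.poisson(_NECROSIS_COUNT_MEAN))
    _plant_components(
        rng, labels, tsi.TUMOR, tsi.NECROSIS, n_nec,
        lambda: rng.integers(2, 8),
    )
    n_itil = int(rng.poisson(_ITIL_COUNT_MEAN))
    _plant_components(
        rng, labels, tsi.TUMOR, tsi.ITIL, n_itil,
        lambda: rng.integers(1, 6),
    )

    # Planted signal: sTIL component count and area shifted for pCR.
    shift = config.effect_size if pcr else 0.0
    count = max(
        0,
        int(round(rng.normal(_STIL_COUNT_MEAN + shift * _STIL_COUNT_SD,
                             _STIL_COUNT_SD))),
    )
    area_mean_target = max(
        1.0, rng.normal(_STIL_AREA_MEAN + shift * _STIL_AREA_SD, _STIL_AREA_SD)
    )
    _plant_components(
        rng, labels, tsi.STROMA, tsi.STIL, count,
        lambda: rng.normal(area_mean_target, 1.0),
        separate=True,
    )
    return TSImage(labels=labels, patient_id=patient_id), float(count), float(
        area_mean_target
    )


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Generate a full synthetic cohort under one configuration.

    Deterministic given the config (including its seed).  When
    0 < pcr_fraction < 1 both outcome groups are guaranteed non-empty.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_pcr = int(round(n * config.pcr_fraction))
    if 0.0 < config.pcr_fraction < 1.0:
        n_pcr = min(max(n_pcr, 1), n - 1)
    statuses = np.array([1] * n_pcr + [0] * (n - n_pcr))
    rng.shuffle(statuses)

    patients = []
    for i, pcr in enumerate(statuses):
        pid = f"SYN{i:04d}"
        ts, planted_count, planted_area = _generate_ts_image(
            rng, config, int(pcr), pid
        )

        er = int(rng.random() < _ER_POS_RATE)
        pr_logit = _PR_BASE_LOGIT + (config.clinical_effect if pcr else 0.0)
        pr = int(rng.random() < 1.0 / (1.0 + math.exp(-pr_logit)))
        er_pct = float(rng.uniform(10, 100)) if er else 0.0
        pr_pct = float(rng.uniform(10, 100)) if pr else 0.0
        her2 = float(np.exp(rng.normal(np.log(3.2), 0.5)))

        if pcr:
            ris = 0.0
        else:
            burden_z = (
                (planted_count - _STIL_COUNT_MEAN) / _STIL_COUNT_SD
                + (planted_area - _STIL_AREA_MEAN) / _STIL_AREA_SD
            ) / math.sqrt(2.0)
            ris = config.ris_scale * math.exp(
                _RIS_SIGMA * rng.normal() - _RIS_COUPLING * burden_z
            )
        patients.append(
            SyntheticPatient(
                patient_id=pid,
                ts_image=ts,
                er_status=er,
                er_percent=er_pct,
                pr_status=pr,
                pr_percent=pr_pct,
                her2_cep17=her2,
                pcr=int(pcr),
                ris=ris,
            )
        )
    return patients


# ---------------------------------------------------------------------------
# RGB tile rendering and rule-based reference classifiers
# ---------------------------------------------------------------------------

# Mean red intensity encodes the class code; green/blue carry loosely
# H&E-like colors.  Red is exactly constant within a tile so the decoder
# is lossless.
_CLASS_GB = {
    tsi.EXCLUDED: (235, 240),
    tsi.TUMOR: (80, 140),
    tsi.STROMA: (160, 180),
    tsi.NECROSIS: (105, 105),
    tsi.ITIL: (60, 150),
    tsi.STIL: (50, 140),
}


def _class_red(code: int) -> int:
    return 230 - 40 * code


def decode_tile_class(tile: np.ndarray) -> int:
    """Invert the mean-red class encoding of a rendered tile."""
    code = int(round((230.0 - float(np.mean(tile[:, :, 0]))) / 40.0))
    if code not in tsi.VALID_CODES:
        raise ValueError(f"tile does not carry a valid class encoding ({code})")
    return code


def render_tile(
    code: int, tile_size: int = 8, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Render one synthetic RGB tile for a compartment code."""
    rng = rng or np.random.default_rng(0)
    tile = np.empty((tile_size, tile_size, 3), dtype=np.uint8)
    tile[:, :, 0] = _class_red(code)
    g, b = _CLASS_GB[code]
    tile[:, :, 1] = np.clip(
        g + rng.integers(-15, 16, size=(tile_size, tile_size)), 0, 255
    )
    tile[:, :, 2] = np.clip(
        b + rng.integers(-15, 16, size=(tile_size, tile_size)), 0, 255
    )
    return tile


def render_tile_mapping(
    ts: TSImage, tile_size: int = 8, seed: int = 0
) -> tuple[dict[tuple[int, int], np.ndarray], tuple[int, int]]:
    """Synthetic tiles for every informative (non-excluded) grid cell.

    Returns the ``{(row, col): tile}`` mapping plus grid shape consumed
    by the classification cascade; excluded cells carry no tile, as they
    would have been dropped by the tissue filter.
    """
    rng = np.random.default_rng(seed)
    tiles = {}
    for r in range(ts.grid_height):
        for c in range(ts.grid_width):
            code = int(ts.labels[r, c])
            if code != tsi.EXCLUDED:
                tiles[(r, c)] = render_tile(code, tile_size, rng)
    return tiles, (ts.grid_height, ts.grid_width)


def render_slide(
    ts: TSImage, tile_size: int = 8, seed: int = 0
) -> np.ndarray:
    """Full synthetic RGB slide (grid cells expanded to pixel tiles)."""
    rng = np.random.default_rng(seed)
    h, w = ts.grid_height * tile_size, ts.grid_width * tile_size
    slide = np.empty((h, w, 3), dtype=np.uint8)
    for r in range(ts.grid_height):
        for c in range(ts.grid_width):
            slide[
                r * tile_size : (r + 1) * tile_size,
                c * tile_size : (c + 1) * tile_size,
            ] = render_tile(int(ts.labels[r, c]), tile_size, rng)
    return slide


class ReferenceTumorClassifier:
    """Tumor-vs-stroma probability from the synthetic class encoding."""

    def predict(self, tile: np.ndarray) -> float:
        return float(
            decode_tile_class(tile) in (tsi.TUMOR, tsi.NECROSIS, tsi.ITIL)
        )


class ReferenceNecrosisClassifier:
    def predict(self, tile: np.ndarray) -> float:
        return float(decode_tile_class(tile) == tsi.NECROSIS)


class ReferenceLymphocyteClassifier:
    def predict(self, tile: np.ndarray) -> float:
        return float(decode_tile_class(tile) in (tsi.ITIL, tsi.STIL))


def reference_classifiers() -> tuple[
    ReferenceTumorClassifier,
    ReferenceNecrosisClassifier,
    ReferenceLymphocyteClassifier,
]:
    """The rule-based classifier triplet for synthetic tiles."""
    return (
        ReferenceTumorClassifier(),
        ReferenceNecrosisClassifier(),
        ReferenceLymphocyteClassifier(),
    )


# ---------------------------------------------------------------------------
# Cohort serialization
# ---------------------------------------------------------------------------

_CLINICAL_COLUMNS = [
    "patient_id", "er", "er_pct", "pr", "pr_pct", "her2_cep17", "pcr", "ris_cm",
]


def write_cohort(
    patients: list[SyntheticPatient],
    directory: str | Path,
    config: CohortConfig | None = None,
) -> Path:
    """Write a cohort to disk; returns the manifest path.

    Layout: one palette PNG label grid (+ JSON sidecar) per patient,
    one ``clinical.csv``, and a ``manifest.json`` echoing the label
    vocabulary and, when given, the generating configuration.  Output is
    deterministic: writing the same cohort twice yields identical bytes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for patient in patients:
        tsi.write_ts_image(patient.ts_image, directory / f"{patient.patient_id}.png")
    with open(directory / "clinical.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CLINICAL_COLUMNS)
        writer.writeheader()
        for patient in patients:
            writer.writerow(patient.clinical_row())
    manifest = {
        "label_codes": {str(k): v for k, v in tsi.LABEL_NAMES.items()},
        "patients": [p.patient_id for p in patients],
        "clinical_csv": "clinical.csv",
        "config": asdict(config) if config is not None else None,
        "seed": config.seed if config is not None else None,
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return manifest_path


def read_cohort(directory: str | Path) -> list[SyntheticPatient]:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    patients = []
    with open(directory / manifest["clinical_csv"], newline="") as fh:
        for row in csv.DictReader(fh):
            pid = row["patient_id"]
            ts = tsi.read_ts_image(directory / f"{pid}.png")
            patients.append(
                SyntheticPatient(
                    patient_id=pid,
                    ts_image=ts,
                    er_status=int(row["er"]),
                    er_percent=float(row["er_pct"]),
                    pr_status=int(row["pr"]),
                    pr_percent=float(row["pr_pct"]),
                    her2_cep17=float(row["her2_cep17"]),
                    pcr=int(row["pcr"]),
                    ris=float(row["ris_cm"]),
                )
            )
    return patients


# ---------------------------------------------------------------------------
# Feature-level cohorts for selection-recovery experiments
# ---------------------------------------------------------------------------

def generate_feature_cohort(
    n_patients: int = 200,
    n_features: int = 51,
    n_informative: int = 3,
    effect_size: float = 1.5,
    pcr_fraction: float = 0.5,
    seed: int = 0,
):
    """Plain feature-matrix cohort with independent planted features.

    The informative columns are standard normal shifted by
    ``effect_size`` for the positive class; the rest are pure noise.
    Returns ``(X, y, informative_names)`` with X a patients x features
    DataFrame — the ground truth against which feature-selection
    recovery is scored.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n_pos = int(round(n_patients * pcr_fraction))
    y = np.array([1] * n_pos + [0] * (n_patients - n_pos))
    rng.shuffle(y)
    X = rng.normal(size=(n_patients, n_features))
    X[y == 1, :n_informative] += effect_size
    names = [f"f{i:02d}" for i in range(n_features)]
    frame = pd.DataFrame(X, columns=names)
    frame.index = [f"SYN{i:04d}" for i in range(n_patients)]
    return frame, pd.Series(y, index=frame.index, name="pcr"), names[:n_informative]
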