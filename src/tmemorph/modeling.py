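"""Feature fusion, LASSO selection, MLP training and evaluation.

The modeling stage fuses per-compartment morphological features with the
five clinical covariates, standardizes them with training-cohort
statistics only, selects features by L1-penalized (LASSO) logistic
regression with the penalty chosen by stratified ten-fold
cross-validated grid search maximizing mean AUC, trains an
L2-regularized multilayer perceptron on the selected features, and
evaluates on a held-out cohort with AUC, F1, PPV, recall and NPV.

All fitting — imputation, scaling, penalty choice, MLP tuning — uses
training rows only; the evaluation cohort enters solely through
``transform`` and the final metric computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier

from .baseline import baseline_table
from .morphology import (
    DEFAULT_SR_THRESHOLD,
    all_feature_names,
    extract_feature_table,
    feature_names,
)

CLINICAL_COLUMNS = ["er", "er_pct", "pr", "pr_pct", "her2_cep17"]

DEFAULT_C_GRID = tuple(np.logspace(-2, 2, 9))
DEFAULT_HIDDEN_GRID = (4, 8, 16)
DEFAULT_ALPHA_GRID = (1e-3, 1e-2, 1e-1)


@dataclass
class ModelConfig:
    """Hyperparameter grids and experiment settings."""

    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    hidden_grid: tuple[int, ...] = DEFAULT_HIDDEN_GRID
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    folds: int = 10
    seed: int = 0
    threshold: float = 0.5


@dataclass
class ModelReport:
    """Selected features with weights plus held-out metrics."""

    selected_features: dict[str, float]
    metrics: dict[str, float]
    threshold: float = 0.5
    training_fraction: float = 1.0
    chosen_c: float | None = None
    mlp_params: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# Clinical encoding and standardization
# ---------------------------------------------------------------------------

def encode_status(value) -> int:
    """Map a receptor status to {0, 1}.

    Accepts 0/1 (or "0"/"1") and case-insensitive strings ending in
    "positive" or "negative" (so "ER-positive", "positive", "POS..." all
    work); anything else raises ``ValueError``.
    """
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return int(value)
    if isinstance(value, (float, np.floating)) and value in (0.0, 1.0):
        return int(value)
    text = str(value).strip().lower()
    if text in {"0", "1"}:
        return int(text)
    if text.endswith("positive"):
        return 1
    if text.endswith("negative"):
        return 0
    raise ValueError(f"unrecognized receptor status {value!r}")


def encode_clinical(raw: pd.DataFrame) -> pd.DataFrame:
    """Numeric clinical covariates: binary ER/PR, pass-through numerics."""
    out = raw.copy()
    for col in ("er", "pr"):
        if col in out.columns:
            out[col] = out[col].map(encode_status)
    for col in ("er_pct", "pr_pct", "her2_cep17"):
        if col in out.columns:
            out[col] = pd.to_numeric(out[col])
    return out


@dataclass
class Standardizer:
    """Train-derived median imputation plus z-scaling (population std)."""

    medians: pd.Series
    means: pd.Series
    stds: pd.Series

    @classmethod
    def fit(cls, train: pd.DataFrame) -> "Standardizer":
        medians = train.median()
        medians = medians.fillna(0.0)  # all-NaN training column
        filled = train.fillna(medians)
        means = filled.mean()
        stds = filled.std(ddof=0)
        return cls(medians=medians, means=means, stds=stds)

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        if list(frame.columns) != list(self.medians.index):
            raise ValueError("column mismatch between fit and transform")
        filled = frame.fillna(self.medians)
        scaled = filled - self.means
        safe = self.stds.replace(0.0, np.nan)
        scaled = scaled / safe
        return scaled.fillna(0.0)  # zero-variance columns map to 0


def standardize_fit_apply(
    train: pd.DataFrame, eval_frame: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, Standardizer]:
    """Standardize both cohorts with training-derived statistics."""
    if len(train) == 0:
        raise ValueError("empty training matrix")
    scaler = Standardizer.fit(train)
    return scaler.transform(train), scaler.transform(eval_frame), scaler


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def rank_auc(y_true, scores) -> float:
    """AUC by rank concordance; tied scores receive half credit.

    Equivalent to the Mann–Whitney U statistic normalized by n1*n0.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes in the evaluation labels")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate_scores(y_true, scores, threshold: float = 0.5) -> dict[str, float]:
    """AUC, F1, PPV, recall and NPV from class-1 scores.

    Hard predictions use ``score >= threshold``.  Ratios with empty
    denominators (e.g. NPV when no sample is predicted negative) are the
    missing sentinel NaN.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    if np.isnan(ppv) or np.isnan(recall) or ppv + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * ppv * recall / (ppv + recall)
    return {
        "auc": rank_auc(y, s),
        "f1": f1,
        "ppv": ppv,
        "recall": recall,
        "npv": npv,
    }


# ---------------------------------------------------------------------------
# LASSO selection and MLP
# ---------------------------------------------------------------------------

def _cv_folds(y: np.ndarray, folds: int, seed: int) -> StratifiedKFold:
    minority = int(min(np.sum(y == 1), np.sum(y == 0)))
    if minority < 2:
        raise ValueError("both classes must appear at least twice")
    if minority < folds:
        warnings.warn(
            f"reducing folds from {folds} to {minority} "
            "(minority class too small)",
            UserWarning,
            stacklevel=3,
        )
        folds = minority
    return StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)


@dataclass
class SelectionResult:
    selected: dict[str, float]
    chosen_c: float
    cv_scores: dict[float, float] = field(default_factory=dict)


def lasso_select(
    X: pd.DataFrame,
    y,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """L1-penalized logistic feature selection, penalty by CV grid search.

    The inverse penalty C is chosen to maximize mean validation AUC over
    stratified folds; ties break toward the stronger penalty (smaller
    C).  Features with non-zero coefficients in the final full-training
    refit are selected; their (standardized-space) coefficients are the
    reported LASSO weights.
    """
    y = np.asarray(y)
    if len(set(y)) < 2:
        raise ValueError("labels contain a single class")
    if len(c_grid) == 0:
        raise ValueError("empty penalty grid")
    skf = _cv_folds(y, folds, seed)
    splits = list(skf.split(X, y))
    cv_scores: dict[float, float] = {}
    for c in sorted(c_grid):
        aucs = []
        for train_idx, val_idx in splits:
            model = _lasso_model(c, seed)
            model.fit(X.iloc[train_idx], y[train_idx])
            scores = model.decision_function(X.iloc[val_idx])
            y_val = y[val_idx]
            if len(set(y_val)) < 2:
                continue
            aucs.append(rank_auc(y_val, scores))
        cv_scores[c] = float(np.mean(aucs)) if aucs else float("nan")
    best_c = max(sorted(cv_scores), key=lambda c: (cv_scores[c], -c))
    final = _lasso_model(best_c, seed)
    final.fit(X, y)
    coefs = final.coef_.ravel()
    selected = {
        name: float(w) for name, w in zip(X.columns, coefs) if w != 0.0
    }
    return SelectionResult(selected=selected, chosen_c=float(best_c),
                           cv_scores=cv_scores)


def _lasso_model(c: float, seed: int) -> LogisticRegression:
    return LogisticRegression(
        l1_ratio=1.0, C=c, solver="liblinear", max_iter=2000, random_state=seed
    )


class ConstantPredictor:
    """Fallback when LASSO selects nothing: probability 0.5 everywhere."""

    def predict_proba(self, X) -> np.ndarray:
        n = len(X)
        return np.column_stack([np.full(n, 0.5), np.full(n, 0.5)])


def train_mlp(
    X: pd.DataFrame,
    y,
    hidden_grid: tuple[int, ...] = DEFAULT_HIDDEN_GRID,
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    folds: int = 10,
    seed: int = 0,
):
    """Single-hidden-layer MLP with L2 weight decay, tuned by CV AUC.

    Hidden size and L2 strength are chosen on the same stratified folds
    as feature selection; ties prefer the smaller network and stronger
    regularization.  Returns ``(fitted_model, best_params)``.
    """
    y = np.asarray(y)
    if len(set(y)) < 2:
        raise ValueError("labels contain a single class")
    skf = _cv_folds(y, folds, seed)
    splits = list(skf.split(X, y))
    best = None
    for hidden in sorted(hidden_grid):
        for alpha in sorted(alpha_grid, reverse=True):
            aucs = []
            with _quiet_convergence():
                for train_idx, val_idx in splits:
                    model = _mlp_model(hidden, alpha, seed)
                    model.fit(X.iloc[train_idx], y[train_idx])
                    y_val = y[val_idx]
                    if len(set(y_val)) < 2:
                        continue
                    scores = model.predict_proba(X.iloc[val_idx])[:, 1]
                    aucs.append(rank_auc(y_val, scores))
            score = float(np.mean(aucs)) if aucs else float("nan")
            if best is None or (not np.isnan(score) and score > best[0]):
                best = (score, hidden, alpha)
    _, hidden, alpha = best
    final = _mlp_model(hidden, alpha, seed)
    with _quiet_convergence():
        final.fit(X, y)
    return final, {"hidden": hidden, "alpha": alpha}


def _mlp_model(hidden: int, alpha: float, seed: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(hidden,),
        alpha=alpha,
        solver="lbfgs",
        max_iter=500,
        random_state=seed,
    )


class _quiet_convergence(warnings.catch_warnings):
    """Silence lbfgs max-iter chatter; capped iterations are intended."""

    def __enter__(self):
        out = super().__enter__()
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        return out


def evaluate(predictor, X: pd.DataFrame, y, threshold: float = 0.5,
             **report_kwargs) -> ModelReport:
    """Score a fitted predictor on held-out features and labels."""
    if len(X) == 0:
        raise ValueError("empty evaluation cohort")
    scores = predictor.predict_proba(X)[:, 1]
    metrics = evaluate_scores(y, scores, threshold)
    return ModelReport(
        selected_features=report_kwargs.pop("selected_features", {}),
        metrics=metrics,
        threshold=threshold,
        **report_kwargs,
    )


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

def run_pipeline(
    train_X: pd.DataFrame,
    train_y,
    eval_X: pd.DataFrame,
    eval_y,
    config: ModelConfig | None = None,
) -> ModelReport:
    """Standardize -> LASSO select -> MLP -> held-out evaluation."""
    config = config or ModelConfig()
    train_s, eval_s, _ = standardize_fit_apply(train_X, eval_X)
    selection = lasso_select(
        train_s, train_y, c_grid=config.c_grid, folds=config.folds,
        seed=config.seed,
    )
    cols = list(selection.selected)
    if cols:
        predictor, mlp_params = train_mlp(
            train_s[cols], train_y,
            hidden_grid=config.hidden_grid, alpha_grid=config.alpha_grid,
            folds=config.folds, seed=config.seed,
        )
        eval_feats = eval_s[cols]
    else:
        predictor, mlp_params = ConstantPredictor(), None
        eval_feats = eval_s
    return evaluate(
        predictor, eval_feats, eval_y, threshold=config.threshold,
        selected_features=selection.selected,
        chosen_c=selection.chosen_c,
        mlp_params=mlp_params,
    )


def assemble_cohort_table(
    patients,
    threshold: float = DEFAULT_SR_THRESHOLD,
) -> pd.DataFrame:
    """Patients x (morphology + baselines + clinical + outcome) table."""
    ts_images = [p.ts_image for p in patients]
    morph = extract_feature_table(ts_images, threshold=threshold)
    base = baseline_table(ts_images)
    clinical = pd.DataFrame(
        [p.clinical_row() for p in patients]
    ).set_index("patient_id")
    clinical = encode_clinical(clinical)
    table = morph.join(base).join(clinical)
    return table


def model_feature_columns(
    compartment: str = "stil", include_clinical: bool = True
) -> list[str]:
    """Feature columns for one compartment model (46 + 5 clinical)."""
    cols = feature_names(compartment)
    if include_clinical:
        cols = cols + CLINICAL_COLUMNS
    return cols


def run_compartment_model(
    train_table: pd.DataFrame,
    eval_table: pd.DataFrame,
    compartment: str = "stil",
    include_clinical: bool = True,
    config: ModelConfig | None = None,
) -> ModelReport:
    """Fit and evaluate the pCR model for one compartment's features."""
    cols = model_feature_columns(compartment, include_clinical)
    return run_pipeline(
        train_table[cols], train_table["pcr"],
        eval_table[cols], eval_table["pcr"],
        config=config,
    )


def training_fraction_curve(
    train_X: pd.DataFrame,
    train_y,
    eval_X: pd.DataFrame,
    eval_y,
    fractions=(0.2, 0.4, 0.6, 0.8, 1.0),
    replicates: int = 10,
    config: ModelConfig | None = None,
) -> list[ModelReport]:
    """Learning-curve experiment against a fixed evaluation cohort.

    For each training fraction, training rows are subsampled with
    stratification (preserving the class balance), the whole
    select-and-train pipeline is rerun, and the model is scored on the
    unchanged evaluation cohort.  Fraction 1.0 uses the full cohort with
    no subsampling.  Each (fraction, replicate) pair runs under its own
    derived seed; reports carry ``training_fraction`` for aggregation.
    """
    config = config or ModelConfig()
    train_y = pd.Series(np.asarray(train_y), index=train_X.index)
    reports = []
    for frac in fractions:
        if not 0.0 < frac <= 1.0:
            raise ValueError(f"fraction {frac} outside (0, 1]")
        for rep in range(replicates):
            sub_seed = int(
                (config.seed * 1_000_003 + rep * 7919 + int(frac * 1000))
                % (2**31 - 1)
            )
            if frac < 1.0:
                sub_X, _, sub_y, _ = train_test_split(
                    train_X, train_y, train_size=frac, stratify=train_y,
                    random_state=sub_seed,
                )
            else:
                sub_X, sub_y = train_X, train_y
            # CV/MLP seed stays fixed; only the subsample varies across
            # replicates, so fraction 1.0 reproduces the full-pipeline run.
            report = run_pipeline(sub_X, sub_y, eval_X, eval_y, config)
            report.training_fraction = frac
            reports.append(report)
    return reports


def threshold_sweep(
    train_patients,
    eval_patients,
    thresholds=(0.01, 0.03, 0.05, 0.10),
    compartments=("stil",),
    include_clinical: bool = True,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Re-run the full pipeline per significant-region threshold.

    Features are re-extracted from the TS-images at each threshold, so
    the sweep exercises the entire morphometry-to-model chain; the
    result is one row per (threshold, compartment) with the five
    held-out metrics.
    """
    rows = []
    for thr in thresholds:
        train_table = assemble_cohort_table(train_patients, threshold=thr)
        eval_table = assemble_cohort_table(eval_patients, threshold=thr)
        for comp in compartments:
            report = run_compartment_model(
                train_table, eval_table, compartment=comp,
                include_clinical=include_clinical, config=config,
            )
            row = {"sr_threshold": thr, "compartment": comp}
            row.update(report.metrics)
            rows.append(row)
    return pd.DataFrame(rows)
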