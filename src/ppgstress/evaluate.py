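"""Regression models and cross-validated evaluation.

Fits four regressor families -- extremely randomized trees, gradient
boosting, k-nearest neighbours, and ordinary least squares -- on each
window-length dataset and scores them by mean 10-fold cross-validated
R-squared against the 1-minute sqrt-stress-index label.  The result is a
model x window-length grid plus a per-length mean row.

Fold assignment is sample-level shuffled k-fold by default, which mirrors
the study protocol but is optimistic: 1-s-stride windows overlap heavily, so
near-duplicate samples appear in both train and test folds.  Passing
``group_by_recording=True`` switches to grouped folds that keep each
recording's windows together, quantifying that optimism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor, GradientBoostingRegressor
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.model_selection import GroupKFold, KFold
from sklearn.neighbors import KNeighborsRegressor

from .dataset import Dataset, FeatureSelectionReport, build_dataset
from .preprocessing import NNISeries

__all__ = [
    "MODEL_NAMES",
    "WINDOW_LENGTHS_S",
    "ModelSpec",
    "CVResult",
    "ExperimentResult",
    "make_model",
    "cross_validate",
    "run_experiment",
    "scatter_export",
    "summarize_grid",
]

MODEL_NAMES: tuple[str, ...] = ("extra_trees", "gradient_boosting", "knn", "linear")
WINDOW_LENGTHS_S: tuple[float, ...] = (5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)


@dataclass(frozen=True)
class ModelSpec:
    """A named regressor with optional hyperparameter overrides.

    Hyperparameters default to the scikit-learn defaults; the seed feeds the
    internal randomness of the tree ensembles.
    """

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"model name must be one of {MODEL_NAMES}, got {self.name!r}")


def make_model(spec: ModelSpec):
    """Instantiate the scikit-learn estimator for a spec."""
    params = dict(spec.hyperparameters)
    if spec.name == "extra_trees":
        return ExtraTreesRegressor(random_state=spec.seed, **params)
    if spec.name == "gradient_boosting":
        return GradientBoostingRegressor(random_state=spec.seed, **params)
    if spec.name == "knn":
        return KNeighborsRegressor(**params)
    return LinearRegression(**params)


@dataclass(frozen=True)
class CVResult:
    mean_r2: float
    fold_scores: tuple[float, ...]
    oof_predictions: np.ndarray  # out-of-fold prediction per sample


def cross_validate(
    dataset: Dataset,
    model: ModelSpec,
    k: int = 10,
    seed: int = 0,
    group_by_recording: bool = False,
) -> CVResult:
    """Mean k-fold CV R-squared of a model on one dataset.

    Returns per-fold scores and one out-of-fold prediction per sample.
    Fully reproducible for a fixed seed (fold shuffling and tree randomness
    are both seeded).
    """
    X, y = dataset.scaled_matrix, dataset.labels
    if len(dataset) < k:
        raise ValueError(f"{len(dataset)} samples < {k} folds")
    if group_by_recording:
        groups = dataset.groups
        if len(np.unique(groups)) < k:
            raise ValueError(f"{len(np.unique(groups))} recordings < {k} grouped folds")
        splitter = GroupKFold(n_splits=k)
        splits = splitter.split(X, y, groups)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)

    scores: list[float] = []
    oof = np.full(len(y), np.nan)
    for train_idx, test_idx in splits:
        est = make_model(model)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        oof[test_idx] = pred
        scores.append(float(r2_score(y[test_idx], pred)))
    return CVResult(
        mean_r2=float(np.mean(scores)),
        fold_scores=tuple(scores),
        oof_predictions=oof,
    )


@dataclass(frozen=True)
class ExperimentResult:
    """Model x window-length grid of mean CV R-squared scores."""

    grid: dict[tuple[str, float], float]
    fold_scores: dict[tuple[str, float], tuple[float, ...]]
    mean_row: dict[float, float]
    n_samples: dict[float, int]
    selection_reports: dict[float, FeatureSelectionReport]
    lengths: tuple[float, ...]
    models: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        """Grid as a table: rows = models plus a Mean row, columns = lengths."""
        data = {
            f"{int(L)} s": [self.grid[(m, L)] for m in self.models] + [self.mean_row[L]]
            for L in self.lengths
        }
        return pd.DataFrame(data, index=list(self.models) + ["mean"])


def summarize_grid(grid: dict[tuple[str, float], float],
                   models: tuple[str, ...],
                   lengths: tuple[float, ...]) -> dict[float, float]:
    """Per-length arithmetic mean of the models' scores (the grid's Mean row)."""
    return {L: float(np.mean([grid[(m, L)] for m in models])) for L in lengths}


def run_experiment(
    nnis: dict[str, NNISeries],
    lengths: tuple[float, ...] = WINDOW_LENGTHS_S,
    models: tuple[str, ...] = MODEL_NAMES,
    k: int = 10,
    seed: int = 0,
    stride: float = 1.0,
    threshold: float = 0.6,
    group_by_recording: bool = False,
) -> ExperimentResult:
    """Build a dataset per window length and cross-validate every model.

    ``nnis`` maps recording id to its preprocessed NN-interval series.
    """
    grid: dict[tuple[str, float], float] = {}
    folds: dict[tuple[str, float], tuple[float, ...]] = {}
    n_samples: dict[float, int] = {}
    reports: dict[float, FeatureSelectionReport] = {}
    for L in lengths:
        ds, report = build_dataset(nnis, L, stride=stride, threshold=threshold)
        n_samples[L] = len(ds)
        reports[L] = report
        for name in models:
            res = cross_validate(
                ds, ModelSpec(name=name, seed=seed), k=k, seed=seed,
                group_by_recording=group_by_recording,
            )
            grid[(name, L)] = res.mean_r2
            folds[(name, L)] = res.fold_scores
    return ExperimentResult(
        grid=grid,
        fold_scores=folds,
        mean_row=summarize_grid(grid, tuple(models), tuple(lengths)),
        n_samples=n_samples,
        selection_reports=reports,
        lengths=tuple(lengths),
        models=tuple(models),
    )


def scatter_export(
    dataset: Dataset,
    model: ModelSpec,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-fold (predicted, actual) sqrt-SI pairs for scatter plotting.

    One prediction per sample, taken from the fold in which the sample was
    held out; the pooled R-squared of these pairs tracks the CV score.
    """
    res = cross_validate(dataset, model, k=k, seed=seed)
    return pd.DataFrame(
        {
            "recording_id": dataset.groups,
            "t_start": [s.t_start for s in dataset.samples],
            "predicted_sqrt_si": res.oof_predictions,
            "actual_sqrt_si": dataset.labels,
        }
    )
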