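"""Cost-weighted linear classifiers for rare flashback scenes.

Flashback scenes are outnumbered roughly 5:1 by potential scenes, so a
plain classifier can look accurate while never calling a flashback.
Both families here accept a misclassification-cost multiplier for the
flashback class (default: the training-set potential:flashback ratio,
i.e. inverse class frequency):

* ``lda`` — linear discriminant analysis with analytic (Ledoit–Wolf
  style) shrinkage of the pooled covariance.  The cost enters through
  the class priors of the Bayes rule: effective priors are proportional
  to class count x cost, which both weights the pooled covariance and
  shifts the decision threshold toward calling flashbacks.
* ``svm`` — linear support vector machine (hinge loss) with per-class
  error costs.

Features are z-scored with training-set statistics stored on the model,
so prediction is invariant to affine rescaling of any input column.
Ties (decision score exactly zero) go to the flashback class, favouring
sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC

from .features import SceneFeatureTable, parse_feature_name
from .windows import FLASHBACK, POTENTIAL

__all__ = [
    "TrainedClassifier",
    "train_weighted_classifier",
    "predict_scenes",
    "select_voxels_ttest",
    "rank_feature_weights",
]

FAMILIES = ("lda", "svm")


@dataclass(frozen=True)
class TrainedClassifier:
    """A fitted linear decision rule in standardized feature space.

    ``weights`` and ``intercept`` act on ``(x - mean) / scale``; a
    non-negative score predicts flashback.
    """

    family: str
    weights: np.ndarray
    intercept: float
    mean: np.ndarray
    scale: np.ndarray
    weighting: float
    feature_names: tuple[str, ...] | None = None

    @property
    def n_features(self) -> int:
        return len(self.weights)

    def _check_width(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"model was trained on {self.n_features} features, got {X.shape[1]}"
            )
        return X

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = self._check_width(X)
        return ((X - self.mean) / self.scale) @ self.weights + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        """String labels per row; empty input yields an empty array."""
        X = self._check_width(X)
        if X.shape[0] == 0:
            return np.array([], dtype=object)
        scores = self.decision_scores(X)
        return np.where(scores >= 0, FLASHBACK, POTENTIAL)


def _as_xy(table) -> tuple[np.ndarray, np.ndarray, tuple[str, ...] | None]:
    if isinstance(table, SceneFeatureTable):
        return table.X, table.y, table.feature_names
    X, y = table
    y = np.asarray(y)
    if y.dtype.kind in "OUS":  # string labels
        y = (y == FLASHBACK).astype(int)
    return np.asarray(X, dtype=float), y.astype(int), None


def train_weighted_classifier(
    table,
    family: str = "lda",
    weighting: float | None = None,
    seed: int = 0,
    C: float = 1.0,
    feature_names: tuple[str, ...] | None = None,
) -> TrainedClassifier:
    """Fit a cost-weighted linear classifier.

    Parameters
    ----------
    table:
        A :class:`~intrumem.features.SceneFeatureTable` or an
        ``(X, y)`` pair (y binary with flashback=1, or string labels).
    family:
        ``"lda"`` or ``"svm"``.
    weighting:
        Cost multiplier (>= 1) for misclassifying a flashback.  ``None``
        uses the training-set potential:flashback count ratio (floored
        at 1).
    seed:
        Funnelled to any stochastic solver component; the fit is
        deterministic given data and seed.
    C:
        SVM regularisation constant (ignored by LDA).
    """
    X, y, names = _as_xy(table)
    if feature_names is not None:
        names = tuple(feature_names)
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    n_fb = int((y == 1).sum())
    n_pot = int((y == 0).sum())
    if n_fb == 0 or n_pot == 0:
        raise ValueError("training rows must contain both classes")
    if weighting is None:
        weighting = max(1.0, n_pot / n_fb)
    weighting = float(weighting)
    if not np.isfinite(weighting) or weighting < 1.0:
        raise ValueError("flashback cost weighting must be finite and >= 1")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Xs = (X - mean) / scale

    if family == "lda":
        raw = np.array([n_pot, n_fb * weighting], dtype=float)
        priors = raw / raw.sum()
        model = LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage="auto", priors=priors
        )
        with warnings.catch_warnings():
            # collinear standardized features are expected; shrinkage handles them
            warnings.simplefilter("ignore", UserWarning)
            model.fit(Xs, y)
        weights = model.coef_[0].astype(float)
        intercept = float(model.intercept_[0])
    else:
        model = SVC(
            kernel="linear",
            C=C,
            class_weight={0: 1.0, 1: weighting},
            tol=1e-6,  # tight so the fit is invariant to training-row order
            random_state=int(seed) % (2**31),
        )
        model.fit(Xs, y)
        weights = model.coef_[0].astype(float)
        intercept = float(model.intercept_[0])

    return TrainedClassifier(
        family=family,
        weights=weights,
        intercept=intercept,
        mean=mean,
        scale=scale,
        weighting=weighting,
        feature_names=names,
    )


def predict_scenes(model: TrainedClassifier, rows) -> np.ndarray:
    """Predict a label per row (flashback/potential).

    Accepts a feature matrix, a :class:`SceneFeatureTable`, or a
    DataFrame holding the model's feature columns.
    """
    if isinstance(rows, SceneFeatureTable):
        X = rows.X
    elif isinstance(rows, pd.DataFrame) and model.feature_names is not None:
        X = rows[list(model.feature_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(rows, dtype=float)
        if X.ndim == 1:
            X = X.reshape(0, model.n_features) if X.size == 0 else X[None, :]
    return model.predict(X)


def select_voxels_ttest(X: np.ndarray, y: np.ndarray, k: int = 1000) -> np.ndarray:
    """Top-k voxels by |two-sample t| between flashback and potential rows.

    The statistic is the pooled-variance (equal-variance) two-sample t
    per voxel.  Ties — and zero-variance voxels, whose t is undefined
    and treated as 0 — are broken by ascending voxel index.  Asking for
    more voxels than exist returns all of them with a warning.  The
    returned indices are in rank order (strongest first).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.dtype.kind in "OUS":
        y = (y == FLASHBACK).astype(int)
    if k < 1:
        raise ValueError("k must be >= 1")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least two scenes of each class for the t-test")
    n_voxels = X.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = stats.ttest_ind(X[y == 1], X[y == 0], axis=0, equal_var=True).statistic
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    order = np.argsort(-np.abs(t), kind="stable")
    if k >= n_voxels:
        if k > n_voxels:
            warnings.warn(
                f"requested {k} voxels but only {n_voxels} exist; returning all",
                stacklevel=2,
            )
        return order
    return order[:k]


def rank_feature_weights(
    model: TrainedClassifier,
    feature_names: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Rank input features by |classifier weight|, annotated by origin.

    Returns a DataFrame (rank, feature, component, window, weight,
    abs_weight) in descending |weight| order.  This is a descriptive
    ranking of the fitted rule, not a statistical test of the features.
    """
    names = feature_names if feature_names is not None else model.feature_names
    if names is None:
        names = tuple(f"f{i}" for i in range(model.n_features))
    if len(names) != model.n_features:
        raise ValueError("feature_names length does not match the weight vector")
    components, windows_ = [], []
    for name in names:
        try:
            comp, tag = parse_feature_name(name)
        except (ValueError, IndexError):
            comp, tag = -1, name
        components.append(comp)
        windows_.append(tag)
    frame = pd.DataFrame(
        {
            "feature": names,
            "component": components,
            "window": windows_,
            "weight": model.weights,
            "abs_weight": np.abs(model.weights),
        }
    )
    frame = frame.sort_values("abs_weight", ascending=False, kind="stable")
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame.reset_index(drop=True)
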