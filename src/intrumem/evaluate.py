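"""Cross-validation protocols, metrics and sweeps.

Two evaluation protocols:

* **Across participants (LOSO)** — leave-one-subject-out: for every
  fold the group ICA, feature standardization and classifier are fit on
  the training participants only; the left-out participant's features
  are obtained by back-projecting the *training* decomposition onto
  their run, and metrics are computed on their scenes.  With the
  per-fold ICA refit this protocol is leakage-free by construction; a
  flag reproduces the cheaper shared-decomposition variant.
* **Within participant** — for one participant with enough flashback
  scenes, every (flashback, potential) scene pair is held out in turn;
  per fold, voxels are selected by a two-sample t-test on the training
  scenes only and a classifier is trained on the remaining scenes.

Metrics follow the imbalanced-design conventions: accuracy is
(TP+TN)/total, and *sensitivity* is the fraction of a participant's
true flashback scenes the classifier identifies — accuracy alone is
uninformative when always answering "potential" is 85% correct.

A permutation null for the LOSO mean sensitivity is provided: diary
labels are shuffled within each training participant and only the
classifier is refit per fold (the features are label-free, so the
decomposition and feature extraction need not be recomputed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import TrainedClassifier, train_weighted_classifier, select_voxels_ttest
from .decompose import (
    GroupDecomposition,
    backproject_components,
    concatenate_runs,
    fit_group_ica,
)
from .features import SceneFeatureTable, extract_scene_features
from .simulate import NetworkSpec, SceneSchedule, SimulationConfig, Study, convolve_events
from .windows import FLASHBACK, POTENTIAL, SCENE_WINDOWS, WINDOW_TAGS

__all__ = [
    "ConfusionCounts",
    "UndefinedMetricError",
    "PipelineConfig",
    "CVReport",
    "compute_accuracy",
    "compute_sensitivity",
    "loso_cross_validation",
    "permutation_null_sensitivity",
    "within_subject_cv",
    "ic_count_sweep",
    "fit_reporting_model",
    "expected_effect_profile",
    "planted_feature_pairs",
]

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """A metric's denominator is empty (no rows, or no positive scenes)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion counts with flashback as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError("prediction and truth lengths differ")
        true_fb = y_true == FLASHBACK
        pred_fb = y_pred == FLASHBACK
        return cls(
            tp=int((true_fb & pred_fb).sum()),
            fn=int((true_fb & ~pred_fb).sum()),
            fp=int((~true_fb & pred_fb).sum()),
            tn=int((~true_fb & ~pred_fb).sum()),
        )

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fn + other.fn, self.fp + other.fp, self.tn + other.tn
        )


def compute_accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / total; undefined on an empty table."""
    if counts.total == 0:
        raise UndefinedMetricError("accuracy is undefined on an empty fold")
    return (counts.tp + counts.tn) / counts.total


def compute_sensitivity(counts: ConfusionCounts) -> float:
    """TP / (TP + FN): true flashbacks identified out of all flashbacks."""
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("sensitivity is undefined without flashback scenes")
    return counts.tp / (counts.tp + counts.fn)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the decoding pipeline used inside a protocol run."""

    n_components: int = 39
    family: str = "lda"
    weighting: float | None = None
    C: float = 1.0
    refit_ica_per_fold: bool = True
    lag: float = 0.0
    ica_max_iter: int = 500
    ica_tol: float = 1e-4
    ica_on_fail: str = "error"


@dataclass(frozen=True)
class FoldData:
    """Cached per-fold matrices, enough to retrain the classifier only."""

    fold: str
    train_X: np.ndarray
    train_y: np.ndarray
    train_participants: np.ndarray
    test_X: np.ndarray
    test_labels: np.ndarray
    feature_names: tuple[str, ...]


@dataclass
class CVReport:
    """Per-fold confusion counts and metrics plus cross-fold summaries.

    ``folds`` has one row per evaluated fold (columns: fold, tp, fn,
    fp, tn, accuracy, sensitivity); folds whose sensitivity is
    undefined carry NaN there and are excluded from the sensitivity
    mean/SE (never imputed).
    """

    protocol: str
    folds: pd.DataFrame
    config: dict
    seed: int
    failures: tuple = ()
    fold_data: list | None = field(default=None, repr=False)
    models: list | None = field(default=None, repr=False)

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    @property
    def pooled(self) -> ConfusionCounts:
        f = self.folds
        return ConfusionCounts(
            int(f["tp"].sum()), int(f["fn"].sum()), int(f["fp"].sum()), int(f["tn"].sum())
        )

    @staticmethod
    def _mean_se(values: pd.Series) -> tuple[float, float]:
        values = values.dropna()
        if len(values) == 0:
            return float("nan"), float("nan")
        mean = float(values.mean())
        se = float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) > 1 else float("nan")
        return mean, se

    @property
    def mean_accuracy(self) -> float:
        return self._mean_se(self.folds["accuracy"])[0]

    @property
    def se_accuracy(self) -> float:
        return self._mean_se(self.folds["accuracy"])[1]

    @property
    def mean_sensitivity(self) -> float:
        return self._mean_se(self.folds["sensitivity"])[0]

    @property
    def se_sensitivity(self) -> float:
        return self._mean_se(self.folds["sensitivity"])[1]

    def summary(self) -> dict:
        pooled = self.pooled
        return {
            "protocol": self.protocol,
            "n_folds": self.n_folds,
            "mean_accuracy": self.mean_accuracy,
            "se_accuracy": self.se_accuracy,
            "mean_sensitivity": self.mean_sensitivity,
            "se_sensitivity": self.se_sensitivity,
            "pooled_accuracy": compute_accuracy(pooled) if pooled.total else float("nan"),
            "pooled_sensitivity": (
                compute_sensitivity(pooled) if pooled.tp + pooled.fn else float("nan")
            ),
            "n_failures": len(self.failures),
            "seed": self.seed,
            **{f"config_{k}": v for k, v in self.config.items()},
        }


# --------------------------------------------------------------------------
# leave-one-subject-out
# --------------------------------------------------------------------------


def _participant_features(
    decomposition: GroupDecomposition, run, study: Study, lag: float
) -> SceneFeatureTable:
    timecourses = backproject_components(decomposition, run)
    return extract_scene_features(timecourses, study.schedule, study.diaries, lag=lag)


def _fold_metrics(test_labels, y_pred) -> dict:
    counts = ConfusionCounts.from_labels(test_labels, y_pred)
    row = {"tp": counts.tp, "fn": counts.fn, "fp": counts.fp, "tn": counts.tn,
           "accuracy": compute_accuracy(counts)}
    if counts.tp + counts.fn == 0:
        logger.info("fold without flashback scenes: sensitivity undefined, excluded")
        row["sensitivity"] = float("nan")
    else:
        row["sensitivity"] = compute_sensitivity(counts)
    return row


def loso_cross_validation(
    study: Study,
    config: PipelineConfig | None = None,
    seed: int = 0,
    return_fold_data: bool = False,
    return_models: bool = False,
) -> CVReport:
    """Leave-one-subject-out evaluation of the full decoding pipeline.

    One fold per participant.  With ``config.refit_ica_per_fold`` (the
    default) the group ICA is refit on the training participants of
    every fold; otherwise a single decomposition of the whole cohort is
    shared across folds.  Fold failures are recorded on the report,
    never silently skipped.
    """
    config = config or PipelineConfig()
    runs = list(study.runs)
    if len(runs) < 2:
        raise ValueError("leave-one-subject-out needs at least two participants")

    shared_tables: dict[str, SceneFeatureTable] = {}
    if not config.refit_ica_per_fold:
        decomposition = fit_group_ica(
            concatenate_runs(runs),
            config.n_components,
            seed=seed,
            max_iter=config.ica_max_iter,
            tol=config.ica_tol,
            on_fail=config.ica_on_fail,
        )
        for run in runs:
            shared_tables[run.participant_id] = _participant_features(
                decomposition, run, study, config.lag
            )

    rows, failures = [], []
    fold_data: list[FoldData] = []
    models: list[TrainedClassifier] = []
    for i, test_run in enumerate(runs):
        pid = test_run.participant_id
        try:
            train_runs = [r for r in runs if r.participant_id != pid]
            if config.refit_ica_per_fold:
                decomposition = fit_group_ica(
                    concatenate_runs(train_runs),
                    config.n_components,
                    seed=seed + i,
                    max_iter=config.ica_max_iter,
                    tol=config.ica_tol,
                    on_fail=config.ica_on_fail,
                )
                train_tables = [
                    _participant_features(decomposition, r, study, config.lag)
                    for r in train_runs
                ]
                test_table = _participant_features(
                    decomposition, test_run, study, config.lag
                )
            else:
                train_tables = [shared_tables[r.participant_id] for r in train_runs]
                test_table = shared_tables[pid]
            train = SceneFeatureTable.concat(train_tables)
            model = train_weighted_classifier(
                train, family=config.family, weighting=config.weighting,
                seed=seed, C=config.C,
            )
            y_pred = model.predict(test_table.X)
            row = {"fold": pid, **_fold_metrics(test_table.labels, y_pred)}
            rows.append(row)
            if return_models:
                models.append(model)
            if return_fold_data:
                fold_data.append(
                    FoldData(
                        fold=pid,
                        train_X=train.X,
                        train_y=train.y,
                        train_participants=train.participant_ids,
                        test_X=test_table.X,
                        test_labels=test_table.labels,
                        feature_names=train.feature_names,
                    )
                )
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
            logger.warning("fold %s failed: %s", pid, exc)
            failures.append((pid, repr(exc)))
    folds = pd.DataFrame(rows, columns=["fold", "tp", "fn", "fp", "tn", "accuracy", "sensitivity"])
    return CVReport(
        protocol="across",
        folds=folds,
        config=asdict(config),
        seed=seed,
        failures=tuple(failures),
        fold_data=fold_data if return_fold_data else None,
        models=models if return_models else None,
    )


def permutation_null_sensitivity(
    fold_data: list[FoldData],
    n_permutations: int = 100,
    seed: int = 0,
    family: str = "lda",
    weighting: float | None = None,
    C: float = 1.0,
) -> np.ndarray:
    """Null distribution of the LOSO mean sensitivity.

    For each permutation, training diary labels are shuffled *within
    each training participant* (preserving everyone's flashback count,
    hence the idiosyncrasy structure) and the classifier alone is refit
    per fold; the test labels stay fixed.  Returns the permuted mean
    sensitivities, one per permutation.
    """
    if not fold_data:
        raise ValueError("fold_data is empty; run LOSO with return_fold_data=True")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        sens = []
        for fd in fold_data:
            y_perm = fd.train_y.copy()
            for pid in pd.unique(fd.train_participants):
                idx = np.nonzero(fd.train_participants == pid)[0]
                y_perm[idx] = y_perm[rng.permutation(idx)]
            model = train_weighted_classifier(
                (fd.train_X, y_perm), family=family, weighting=weighting,
                seed=seed, C=C,
            )
            y_pred = model.predict(fd.test_X)
            counts = ConfusionCounts.from_labels(fd.test_labels, y_pred)
            if counts.tp + counts.fn > 0:
                sens.append(compute_sensitivity(counts))
        null[b] = float(np.mean(sens))
    return null


# --------------------------------------------------------------------------
# within participant
# --------------------------------------------------------------------------


def within_subject_cv(
    features: pd.DataFrame,
    labels: pd.Series,
    k: int = 1000,
    family: str = "svm",
    weighting: float | None = None,
    C: float = 1.0,
    min_flashbacks: int = 4,
    seed: int = 0,
) -> CVReport:
    """Leave-one-flashback-and-one-potential-out, for one participant.

    ``features`` is the scenes x voxels table from
    :func:`~intrumem.features.extract_voxel_scene_features`; ``labels``
    maps scene_id to flashback/potential.  Folds enumerate every
    (flashback, potential) pair; per fold the top-``k`` voxels by
    two-sample t are selected on the training scenes only, the
    classifier is trained on those scenes and the held-out pair is
    predicted.  Requires ``min_flashbacks`` flashback scenes (the
    eligibility rule) and at least two scenes per class.
    """
    labels = labels.reindex(features.index)
    if labels.isna().any():
        raise ValueError("every scene in the feature table needs a label")
    fb_ids = labels.index[labels == FLASHBACK]
    pot_ids = labels.index[labels == POTENTIAL]
    if len(fb_ids) < max(2, min_flashbacks) or len(pot_ids) < 2:
        raise ValueError(
            f"participant ineligible: {len(fb_ids)} flashback / {len(pot_ids)} "
            f"potential scenes (need >= {max(2, min_flashbacks)} and >= 2)"
        )
    X = features.to_numpy(dtype=float)
    pos = {scene: i for i, scene in enumerate(features.index)}
    rows = []
    for fb in fb_ids:
        for pot in pot_ids:
            held = {fb, pot}
            train_idx = np.array([pos[s] for s in features.index if s not in held])
            test_idx = np.array([pos[fb], pos[pot]])
            y_train = (labels.iloc[train_idx] == FLASHBACK).to_numpy(int)
            voxels = select_voxels_ttest(X[train_idx], y_train, k=k)
            model = train_weighted_classifier(
                (X[np.ix_(train_idx, voxels)], y_train),
                family=family, weighting=weighting, seed=seed, C=C,
            )
            y_pred = model.predict(X[np.ix_(test_idx, voxels)])
            row = {
                "fold": f"{fb}|{pot}",
                **_fold_metrics(np.array([FLASHBACK, POTENTIAL]), y_pred),
                "n_voxels": len(voxels),
            }
            rows.append(row)
    folds = pd.DataFrame(
        rows,
        columns=["fold", "tp", "fn", "fp", "tn", "accuracy", "sensitivity", "n_voxels"],
    )
    return CVReport(
        protocol="within",
        folds=folds,
        config={"k": k, "family": family, "weighting": weighting, "C": C,
                "min_flashbacks": min_flashbacks},
        seed=seed,
    )


# --------------------------------------------------------------------------
# component-count sweep and reporting model
# --------------------------------------------------------------------------


def ic_count_sweep(
    study: Study,
    ic_counts,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """LOSO performance as a function of the number of ICA components.

    Runs :func:`loso_cross_validation` once per requested count and
    tabulates the cross-fold mean accuracy and sensitivity.
    """
    config = config or PipelineConfig()
    rows = []
    for count in ic_counts:
        report = loso_cross_validation(
            study, replace(config, n_components=int(count)), seed=seed
        )
        rows.append(
            {
                "n_components": int(count),
                "mean_accuracy": report.mean_accuracy,
                "se_accuracy": report.se_accuracy,
                "mean_sensitivity": report.mean_sensitivity,
                "se_sensitivity": report.se_sensitivity,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReportingModel:
    """Whole-cohort decomposition, feature table and classifier.

    The descriptive counterpart of the cross-validated analyses: the
    model whose feature weights are ranked to name predictive networks.
    """

    decomposition: GroupDecomposition
    table: SceneFeatureTable
    model: TrainedClassifier


def fit_reporting_model(
    study: Study, config: PipelineConfig | None = None, seed: int = 0
) -> ReportingModel:
    """Fit the pipeline on the full cohort (no held-out participant)."""
    config = config or PipelineConfig()
    decomposition = fit_group_ica(
        concatenate_runs(list(study.runs)),
        config.n_components,
        seed=seed,
        max_iter=config.ica_max_iter,
        tol=config.ica_tol,
        on_fail=config.ica_on_fail,
    )
    tables = [
        _participant_features(decomposition, run, study, config.lag)
        for run in study.runs
    ]
    table = SceneFeatureTable.concat(tables)
    model = train_weighted_classifier(
        table, family=config.family, weighting=config.weighting, seed=seed, C=config.C
    )
    return ReportingModel(decomposition=decomposition, table=table, model=model)


# --------------------------------------------------------------------------
# ground-truth utilities for planted-signal checks
# --------------------------------------------------------------------------


def expected_effect_profile(
    networks,
    schedule: SceneSchedule,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Window-averaged convolved flashback effect per predictive network.

    For a canonical scene of the schedule's mean duration, the planted
    neural effect boxcars are convolved with the HRF and averaged over
    each analysis window, giving the BOLD-level effect each feature
    would carry.  Because of hemodynamic delay the initial-window
    average of a scene-locked effect is near zero even though the
    neural effect starts at scene onset.
    """
    duration = float(np.mean(schedule.durations))
    onset = 60.0
    run_length = onset + duration + 60.0
    n_frames = int(math.ceil(run_length / config.tr))
    from .features import window_samples  # local import: avoids a module cycle

    rows = {}
    for net in networks:
        if not net.is_predictive:
            continue
        onsets, durations_, amplitudes = [], [], []
        for window, eff in zip(SCENE_WINDOWS, net.flashback_effect):
            if eff == 0.0:
                continue
            start, end = window.bounds(onset, duration)
            if end > start:
                onsets.append(start)
                durations_.append(end - start)
                amplitudes.append(eff)
        regressor = convolve_events(
            onsets, durations_, amplitudes, config.tr, n_frames,
            hrf_model=config.hrf_model, oversampling=config.hrf_oversampling,
        )
        profile = {}
        for window in SCENE_WINDOWS:
            idx = window_samples(window, onset, duration, config.tr, n_frames)
            profile[window.tag] = float(np.abs(regressor[idx]).mean()) if len(idx) else 0.0
        rows[net.component_id] = profile
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(WINDOW_TAGS))
    frame.index.name = "component_id"
    return frame


def planted_feature_pairs(
    networks,
    schedule: SceneSchedule,
    config: SimulationConfig,
    threshold: float | None = None,
) -> set[tuple[int, str]]:
    """(network, window) pairs where the planted effect concentrates.

    By default each predictive network contributes its *dominant*
    window (argmax of the expected window-averaged BOLD effect) — the
    parameter-free notion of "the window the effect was planted in" as
    seen through the HRF.  With ``threshold`` set, every window holding
    at least that fraction of the network's peak qualifies instead;
    note that a multivariate classifier deliberately decorrelates
    redundant windows, so secondary windows need not be top-weighted.
    """
    profile = expected_effect_profile(networks, schedule, config)
    pairs: set[tuple[int, str]] = set()
    for component_id, row in profile.iterrows():
        peak = row.max()
        if peak <= 0:
            continue
        if threshold is None:
            pairs.add((int(component_id), str(row.idxmax())))
        else:
            for tag, value in row.items():
                if value >= threshold * peak:
                    pairs.add((int(component_id), str(tag)))
    return pairs
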