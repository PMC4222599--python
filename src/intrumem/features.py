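"""Scene-level classifier features.

Turns component time courses plus scene timings into the classifier's
input table: for every (participant, scene) row the mean activation of
each group component over three scene-relative windows — the first 6 s
of the scene, the remaining scene duration, and the 12 s after the
scene ends.  With k components this is k x 3 features per scene.  A
voxel-level variant averages raw voxel time courses over the whole
scene, for the within-participant analysis.

A timepoint acquired at ``i * TR`` belongs to a window ``[start, end)``
iff ``start <= i*TR < end`` (half-open, so adjacent windows never share
a sample).  No hemodynamic lag is applied by default; ``lag`` shifts
every window by a constant if desired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decompose import ComponentTimecourses
from .simulate import BoldRun, DiaryLabels, SceneSchedule
from .windows import FLASHBACK, SCENE_WINDOWS, WINDOW_TAGS, WindowDefinition

__all__ = [
    "SceneFeatureTable",
    "window_samples",
    "extract_scene_features",
    "extract_voxel_scene_features",
    "feature_name",
    "parse_feature_name",
]

logger = logging.getLogger(__name__)

_EPS = 1e-9
_META_COLUMNS = ("participant_id", "scene_id", "label")


def feature_name(component: int, window_tag: str) -> str:
    return f"c{component:02d}_{window_tag}"


def parse_feature_name(name: str) -> tuple[int, str]:
    comp, tag = name.split("_", 1)
    return int(comp[1:]), tag


@dataclass(frozen=True)
class SceneFeatureTable:
    """One row per (participant, scene): k x 3 window features plus label."""

    frame: pd.DataFrame
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = [c for c in (*_META_COLUMNS, *self.feature_names) if c not in self.frame]
        if missing:
            raise ValueError(f"feature table is missing columns {missing}")
        if self.frame[list(self.feature_names)].isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.feature_names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Binary labels, flashback = 1."""
        return (self.frame["label"] == FLASHBACK).to_numpy(dtype=int)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    @property
    def participant_ids(self) -> np.ndarray:
        return self.frame["participant_id"].to_numpy()

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def metadata(self) -> list[tuple[int, str]]:
        """(component, window) per feature column."""
        return [parse_feature_name(name) for name in self.feature_names]

    @classmethod
    def concat(cls, tables: list["SceneFeatureTable"]) -> "SceneFeatureTable":
        if not tables:
            raise ValueError("nothing to concatenate")
        names = tables[0].feature_names
        if any(t.feature_names != names for t in tables):
            raise ValueError("feature tables have mismatching columns")
        return cls(
            frame=pd.concat([t.frame for t in tables], ignore_index=True),
            feature_names=names,
        )


def window_samples(
    window: WindowDefinition,
    onset: float,
    duration: float,
    tr: float,
    n_timepoints: int,
    lag: float = 0.0,
) -> np.ndarray:
    """Indices of acquisitions falling inside a scene window.

    Timepoint ``i`` (acquired at ``i*tr``) is included iff its time lies
    in the half-open window ``[start, end)``.  An empty result is legal
    (e.g. the remainder window of a 6 s scene); a window lying entirely
    past the end of the run raises a range error.
    """
    start, end = window.bounds(onset, duration)
    start += lag
    end += lag
    run_end = n_timepoints * tr
    if start >= run_end - _EPS and end > start:
        raise ValueError(
            f"window {window.tag!r} of scene at {onset:.1f} s starts at "
            f"{start:.1f} s, past the end of the run ({run_end:.1f} s)"
        )
    times = np.arange(n_timepoints) * tr
    mask = (times >= start - _EPS) & (times < end - _EPS)
    return np.nonzero(mask)[0]


def extract_scene_features(
    timecourses: ComponentTimecourses,
    schedule: SceneSchedule,
    labels: DiaryLabels | pd.Series,
    windows: tuple[WindowDefinition, ...] = SCENE_WINDOWS,
    lag: float = 0.0,
) -> SceneFeatureTable:
    """Window-averaged component activations for every scene of one run.

    Each feature is the arithmetic mean of a component's time course
    over the window's sample indices.  A scene whose remainder window
    holds no sample reuses the initial-window mean (keeps the table
    rectangular); a scene too short to contain a single initial-window
    sample is an error.
    """
    if isinstance(labels, DiaryLabels):
        labels = labels.for_participant(timecourses.participant_id)
    values = timecourses.values
    n_time = timecourses.n_timepoints
    names = tuple(
        feature_name(c, w.tag) for c in range(timecourses.n_components) for w in windows
    )
    rows = []
    for onset, duration, scene_id in zip(
        schedule.onsets, schedule.durations, schedule.scene_ids
    ):
        window_means: dict[str, np.ndarray] = {}
        for window in windows:
            idx = window_samples(window, onset, duration, timecourses.tr, n_time, lag=lag)
            if len(idx) == 0:
                if window.tag == "initial6":
                    raise ValueError(
                        f"scene {scene_id} (onset {onset:.1f} s, duration "
                        f"{duration:.1f} s) holds no acquisition in its initial "
                        "window; scene unusable"
                    )
                if window.tag == "remainder":
                    logger.info(
                        "scene %s: empty remainder window, reusing initial6 mean",
                        scene_id,
                    )
                    window_means[window.tag] = window_means["initial6"]
                    continue
                raise ValueError(
                    f"scene {scene_id}: window {window.tag!r} holds no acquisition"
                )
            window_means[window.tag] = values[:, idx].mean(axis=1)
        row: dict[str, object] = {
            "participant_id": timecourses.participant_id,
            "scene_id": scene_id,
            "label": labels.loc[scene_id],
        }
        for c in range(timecourses.n_components):
            for window in windows:
                row[feature_name(c, window.tag)] = window_means[window.tag][c]
        rows.append(row)
    frame = pd.DataFrame(rows)
    return SceneFeatureTable(frame=frame, feature_names=names)


def extract_voxel_scene_features(
    run: BoldRun,
    schedule: SceneSchedule,
    voxel_subset: np.ndarray | None = None,
) -> pd.DataFrame:
    """Whole-scene mean of each voxel's time course, per scene.

    Returns a scenes x voxels DataFrame (index scene_id, columns flat
    voxel indices).  ``voxel_subset`` restricts and orders the columns;
    by default all voxels are returned.
    """
    flat = run.flat()  # (T, V)
    if voxel_subset is None:
        voxel_subset = np.arange(flat.shape[1])
    else:
        voxel_subset = np.asarray(voxel_subset, dtype=int)
        if voxel_subset.size == 0:
            raise ValueError("voxel_subset must be non-empty")
    times = np.arange(run.n_timepoints) * run.tr
    rows = []
    for onset, duration, scene_id in zip(
        schedule.onsets, schedule.durations, schedule.scene_ids
    ):
        mask = (times >= onset - _EPS) & (times < onset + duration - _EPS)
        if not mask.any():
            raise ValueError(
                f"scene {scene_id} holds no acquisition (duration "
                f"{duration:.1f} s < one TR of {run.tr:.1f} s)"
            )
        rows.append(flat[mask][:, voxel_subset].mean(axis=0))
    return pd.DataFrame(rows, index=pd.Index(schedule.scene_ids, name="scene_id"),
                        columns=voxel_subset)
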