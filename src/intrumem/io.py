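"""Reading and writing the package's on-disk formats.

BOLD runs and spatial maps travel as NIfTI-1 (4D, TR recorded in the
header's fourth zoom); event and diary tables as tab-separated text
with seconds from run start; feature tables, time courses and CV
reports as TSV; fitted classifiers as a documented key=value text file.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .classify import TrainedClassifier
from .decompose import ComponentTimecourses, GroupDecomposition
from .features import SceneFeatureTable, _META_COLUMNS
from .simulate import BoldRun, DiaryLabels, SceneSchedule, Study

__all__ = [
    "save_bold", "load_bold",
    "save_schedule", "load_schedule",
    "save_diaries", "load_diaries",
    "save_feature_table", "load_feature_table",
    "save_decomposition", "load_decomposition",
    "save_timecourses", "load_timecourses",
    "model_to_text", "model_from_text", "save_model", "load_model",
    "save_cv_report",
    "save_study", "load_study",
]

_VOXEL_MM = 3.0  # nominal isotropic voxel size recorded in headers


def save_bold(run: BoldRun, path) -> None:
    affine = np.diag([_VOXEL_MM, _VOXEL_MM, _VOXEL_MM, 1.0])
    img = nib.Nifti1Image(run.data, affine)
    img.header.set_zooms((_VOXEL_MM, _VOXEL_MM, _VOXEL_MM, run.tr))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_bold(path, participant_id: str | None = None) -> BoldRun:
    path = Path(path)
    img = nib.load(str(path))
    tr = float(img.header.get_zooms()[3])
    if participant_id is None:
        participant_id = path.name.split(".")[0]
    return BoldRun(participant_id=participant_id, data=np.asarray(img.get_fdata()), tr=tr)


def save_schedule(schedule: SceneSchedule, path) -> None:
    path = Path(path)
    schedule.to_frame().to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"run_duration": schedule.run_duration}))


def load_schedule(path, run_duration: float | None = None) -> SceneSchedule:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    if run_duration is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            run_duration = json.loads(sidecar.read_text())["run_duration"]
        else:
            raise ValueError("run_duration not given and no sidecar found")
    return SceneSchedule.from_frame(frame, run_duration=run_duration)


def save_diaries(diaries: DiaryLabels, path) -> None:
    diaries.frame.to_csv(path, sep="\t", index=False)


def load_diaries(path) -> DiaryLabels:
    return DiaryLabels(pd.read_csv(path, sep="\t"))


def save_feature_table(table: SceneFeatureTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def load_feature_table(path) -> SceneFeatureTable:
    frame = pd.read_csv(path, sep="\t")
    names = tuple(c for c in frame.columns if c not in _META_COLUMNS)
    return SceneFeatureTable(frame=frame, feature_names=names)


def save_decomposition(decomposition: GroupDecomposition, path) -> None:
    """Spatial maps as a 4D NIfTI (component = 4th axis) + JSON sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(decomposition.maps_4d(), np.diag([_VOXEL_MM] * 3 + [1.0]))
    nib.save(img, str(path))
    sidecar = path.with_name(path.name.split(".")[0] + "_meta.json")
    sidecar.write_text(
        json.dumps(
            {
                "explained_variance": decomposition.explained_variance.tolist(),
                "seed": decomposition.seed,
                "n_iter": decomposition.n_iter,
                "converged": decomposition.converged,
            }
        )
    )


def load_decomposition(path) -> GroupDecomposition:
    path = Path(path)
    img = nib.load(str(path))
    maps4d = np.asarray(img.get_fdata())
    grid_shape = maps4d.shape[:3]
    maps = maps4d.reshape(-1, maps4d.shape[3]).T
    sidecar = path.with_name(path.name.split(".")[0] + "_meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return GroupDecomposition(
        spatial_maps=maps,
        grid_shape=grid_shape,
        explained_variance=np.asarray(meta.get("explained_variance", [np.nan] * maps.shape[0])),
        seed=int(meta.get("seed", -1)),
        n_iter=int(meta.get("n_iter", -1)),
        converged=bool(meta.get("converged", True)),
    )


def save_timecourses(timecourses: ComponentTimecourses, path) -> None:
    path = Path(path)
    frame = pd.DataFrame(
        timecourses.values,
        index=pd.Index(range(timecourses.n_components), name="component"),
    )
    frame.to_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"participant_id": timecourses.participant_id, "tr": timecourses.tr})
    )


def load_timecourses(path) -> ComponentTimecourses:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col="component")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ComponentTimecourses(
        participant_id=meta["participant_id"],
        values=frame.to_numpy(dtype=float),
        tr=float(meta["tr"]),
    )


def _array_line(values: np.ndarray) -> str:
    return ",".join(repr(float(v)) for v in np.asarray(values, dtype=float))


def model_to_text(model: TrainedClassifier) -> str:
    """Serialize a trained classifier to a key=value text block.

    Floats are written with full repr precision, so identical models
    serialize to identical text (used by the leakage checks).
    """
    lines = [
        f"family={model.family}",
        f"weighting={model.weighting!r}",
        f"intercept={model.intercept!r}",
        f"weights={_array_line(model.weights)}",
        f"mean={_array_line(model.mean)}",
        f"scale={_array_line(model.scale)}",
    ]
    if model.feature_names is not None:
        lines.append("feature_names=" + ",".join(model.feature_names))
    return "\n".join(lines) + "\n"


def model_from_text(text: str) -> TrainedClassifier:
    fields: dict[str, str] = {}
    for line in text.strip().splitlines():
        key, _, value = line.partition("=")
        fields[key] = value
    arr = lambda key: np.array([float(v) for v in fields[key].split(",")])  # noqa: E731
    return TrainedClassifier(
        family=fields["family"],
        weights=arr("weights"),
        intercept=float(fields["intercept"]),
        mean=arr("mean"),
        scale=arr("scale"),
        weighting=float(fields["weighting"]),
        feature_names=tuple(fields["feature_names"].split(","))
        if "feature_names" in fields
        else None,
    )


def save_model(model: TrainedClassifier, path) -> None:
    Path(path).write_text(model_to_text(model))


def load_model(path) -> TrainedClassifier:
    return model_from_text(Path(path).read_text())


def save_cv_report(report, out_dir) -> None:
    """Per-fold TSV plus a JSON summary block."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.folds.to_csv(out_dir / "folds.tsv", sep="\t", index=False)
    (out_dir / "summary.json").write_text(json.dumps(report.summary(), indent=2, default=str))


def save_study(study: Study, out_dir) -> None:
    """Write a study as NIfTI runs plus events/diary tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_schedule(study.schedule, out_dir / "scenes.tsv")
    save_diaries(study.diaries, out_dir / "diaries.tsv")
    for run in study.runs:
        save_bold(run, out_dir / f"{run.participant_id}_bold.nii")


def load_study(out_dir) -> tuple[list[BoldRun], SceneSchedule, DiaryLabels]:
    """Load runs, schedule and diaries written by :func:`save_study`."""
    out_dir = Path(out_dir)
    schedule = load_schedule(out_dir / "scenes.tsv")
    diaries = load_diaries(out_dir / "diaries.tsv")
    runs = [
        load_bold(p, participant_id=p.name.replace("_bold.nii", ""))
        for p in sorted(out_dir.glob("*_bold.nii"))
    ]
    return runs, schedule, diaries
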