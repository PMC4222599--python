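"""Synthetic multi-participant event-related BOLD studies.

This module generates data with the statistical structure the decoding
pipeline assumes, so that every downstream stage can be tested against
known ground truth.  The emulated experiment: each participant watches a
single film run containing ``n_scenes`` emotional scenes (default 20);
over the following week a diary records which scenes returned as
intrusive memories.  Scenes that intruded for a participant are that
participant's *flashback* scenes, the rest are *potential* scenes (they
intruded for someone else).  On average about 3 of 20 scenes become
flashbacks (per-scene intrusion probability 0.15), giving roughly a 5:1
potential:flashback imbalance; participants reporting zero intrusions
are excluded (here: resampled).

Signal model
------------
Each of ``K`` spatial networks (:class:`NetworkSpec`) has a fixed
spatial map over the voxel grid and a neural amplitude time course:

* during every scene the network is driven at ``baseline_amplitude``
  plus an i.i.d. Gaussian per-(participant, scene, network) jitter
  (``SimulationConfig.amplitude_jitter``) — scene-to-scene variation in
  engagement, which is also what renders the networks separable by a
  group decomposition;
* on that participant's flashback scenes, predictive networks receive
  an additional boxcar of height ``flashback_effect[w]`` in each of the
  three scene windows (initial 6 s, remainder, 12 s post scene).

The summed neural time course is convolved with the canonical SPM
double-gamma HRF (peak ~6 s, undershoot ~16 s) and multiplied into the
network's spatial map; i.i.d. Gaussian voxel noise is added.  The model
is linear, so regressing the known convolved design on noiseless data
recovers the planted amplitudes exactly — the main oracle used by the
test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from nilearn.glm.first_level import compute_regressor

from .windows import FLASHBACK, POTENTIAL, SCENE_WINDOWS, WINDOW_TAGS

__all__ = [
    "SceneSchedule",
    "DiaryLabels",
    "NetworkSpec",
    "SimulationConfig",
    "BoldRun",
    "Study",
    "make_scene_schedule",
    "sample_diaries",
    "make_networks",
    "simulate_participant_bold",
    "simulate_study",
    "default_config",
    "default_networks",
    "default_study",
    "null_study",
    "convolve_events",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneSchedule:
    """Timing table of the film's possible scenes.

    Onsets are seconds from run start, strictly increasing; scenes do
    not overlap and fit within ``run_duration``.
    """

    onsets: np.ndarray
    durations: np.ndarray
    scene_ids: np.ndarray
    run_duration: float

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        scene_ids = np.asarray(self.scene_ids, dtype=int)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "scene_ids", scene_ids)
        if not (len(onsets) == len(durations) == len(scene_ids)):
            raise ValueError("onsets, durations and scene_ids must have equal length")
        if len(onsets) == 0:
            raise ValueError("schedule must contain at least one scene")
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("scene onsets must be strictly increasing")
        if np.any(durations <= 0):
            raise ValueError("scene durations must be positive")
        offsets = onsets + durations
        if np.any(offsets[:-1] > onsets[1:]):
            raise ValueError("scenes overlap")
        if offsets[-1] > self.run_duration + 1e-9:
            raise ValueError(
                f"last scene ends at {offsets[-1]:.1f} s but the run is only "
                f"{self.run_duration:.1f} s long"
            )
        if len(np.unique(scene_ids)) != len(scene_ids):
            raise ValueError("scene_ids must be unique")

    @property
    def n_scenes(self) -> int:
        return len(self.onsets)

    @property
    def offsets(self) -> np.ndarray:
        return self.onsets + self.durations

    def to_frame(self) -> pd.DataFrame:
        """Events table (onset, duration, scene_id), seconds from run start."""
        return pd.DataFrame(
            {"onset": self.onsets, "duration": self.durations, "scene_id": self.scene_ids}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, run_duration: float) -> "SceneSchedule":
        return cls(
            onsets=frame["onset"].to_numpy(float),
            durations=frame["duration"].to_numpy(float),
            scene_ids=frame["scene_id"].to_numpy(int),
            run_duration=float(run_duration),
        )


@dataclass(frozen=True)
class DiaryLabels:
    """Per-participant flashback/potential assignment for every scene.

    Wraps a long-format table with columns ``participant_id``,
    ``scene_id`` and ``label`` (one row per pair).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"participant_id", "scene_id", "label"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"diary table needs columns {sorted(required)}")
        bad = set(self.frame["label"].unique()) - {FLASHBACK, POTENTIAL}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
        if self.frame.duplicated(["participant_id", "scene_id"]).any():
            raise ValueError("more than one label for some (participant, scene)")

    def participants(self) -> list:
        return list(pd.unique(self.frame["participant_id"]))

    def for_participant(self, participant_id) -> pd.Series:
        """Labels of one participant, indexed by scene_id."""
        sub = self.frame[self.frame["participant_id"] == participant_id]
        if sub.empty:
            raise KeyError(f"no diary rows for participant {participant_id!r}")
        return sub.set_index("scene_id")["label"]

    def flashback_scenes(self, participant_id) -> np.ndarray:
        labels = self.for_participant(participant_id)
        return labels.index[labels == FLASHBACK].to_numpy()

    def flashback_counts(self) -> pd.Series:
        """Number of flashback scenes per participant."""
        return (
            self.frame.assign(is_fb=self.frame["label"] == FLASHBACK)
            .groupby("participant_id", sort=False)["is_fb"]
            .sum()
        )

    def class_counts(self) -> pd.Series:
        return self.frame["label"].value_counts()


@dataclass(frozen=True)
class NetworkSpec:
    """One spatial network of the generative model.

    ``flashback_effect`` is the additive neural amplitude applied on
    flashback scenes in each window, ordered as :data:`WINDOW_TAGS`
    (initial 6 s, remainder, 12 s post).  All-zero for non-predictive
    networks.
    """

    component_id: int
    spatial_map: np.ndarray
    baseline_amplitude: float
    flashback_effect: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "spatial_map", np.asarray(self.spatial_map, dtype=float))
        if self.spatial_map.ndim != 3:
            raise ValueError("spatial_map must be a 3D array")
        if len(self.flashback_effect) != len(WINDOW_TAGS):
            raise ValueError("flashback_effect must have one entry per window")

    @property
    def is_predictive(self) -> bool:
        return any(e != 0.0 for e in self.flashback_effect)

    @property
    def flat_map(self) -> np.ndarray:
        return self.spatial_map.reshape(-1)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the emulated experiment: 35 participants, 20 scenes
    of 10–20 s separated by 12 s gaps, TR 3 s, per-scene intrusion
    probability 0.15 (expected 3 flashbacks of 20).
    """

    n_participants: int = 35
    n_scenes: int = 20
    grid_shape: tuple[int, int, int] = (20, 20, 10)
    tr: float = 3.0
    intrusion_prob: float = 0.15
    noise_sd: float = 1.0
    scene_duration_range: tuple[float, float] = (10.0, 20.0)
    inter_scene_gap: float = 12.0
    initial_rest: float = 12.0
    post_run_tail: float = 12.0
    amplitude_jitter: float = 5.0
    hrf_model: str = "spm"
    hrf_oversampling: int = 16
    run_duration: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_scenes < 1:
            raise ValueError("participant and scene counts must be positive")
        if not (0.0 < self.intrusion_prob < 1.0):
            raise ValueError("intrusion_prob must lie strictly inside (0, 1)")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if any(n < 1 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be three positive voxel counts")
        if self.noise_sd < 0 or self.amplitude_jitter < 0:
            raise ValueError("noise_sd and amplitude_jitter must be non-negative")
        lo, hi = self.scene_duration_range
        if not (0 < lo <= hi):
            raise ValueError("scene_duration_range must satisfy 0 < lo <= hi")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


@dataclass(frozen=True)
class BoldRun:
    """One participant's 4D BOLD time series (x, y, z, time), plus TR."""

    participant_id: str
    data: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 4:
            raise ValueError("BOLD data must be 4D (three spatial axes x time)")
        if not np.all(np.isfinite(data)):
            raise ValueError("BOLD data contains non-finite values")
        if self.tr <= 0:
            raise ValueError("TR must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def flat(self) -> np.ndarray:
        """Time x voxels view of the run."""
        return self.data.reshape(-1, self.n_timepoints).T


@dataclass(frozen=True)
class Study:
    """A complete synthetic study: runs, timings, diary and ground truth."""

    runs: tuple[BoldRun, ...]
    schedule: SceneSchedule
    diaries: DiaryLabels
    networks: tuple[NetworkSpec, ...]
    config: SimulationConfig

    @property
    def participant_ids(self) -> list[str]:
        return [run.participant_id for run in self.runs]

    def run_for(self, participant_id: str) -> BoldRun:
        for run in self.runs:
            if run.participant_id == participant_id:
                return run
        raise KeyError(participant_id)


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------


def _rng_from(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, stream]))


def _n_frames(run_duration: float, tr: float) -> int:
    return int(math.ceil(run_duration / tr - 1e-9))


def convolve_events(
    onsets,
    durations,
    amplitudes,
    tr: float,
    n_frames: int,
    hrf_model: str = "spm",
    oversampling: int = 16,
) -> np.ndarray:
    """Convolve amplitude-weighted boxcars with the canonical HRF.

    Returns the regressor sampled at acquisition times ``i*tr``; linear
    in the amplitudes (so sums of calls equal calls on merged events).
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    frame_times = np.arange(n_frames) * tr
    exp_condition = np.vstack([onsets, durations, amplitudes])
    regressor, _ = compute_regressor(
        exp_condition, hrf_model, frame_times, oversampling=oversampling
    )
    return regressor[:, 0]


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def make_scene_schedule(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SceneSchedule:
    """Draw a non-overlapping scene schedule for the film run.

    Scene durations are uniform over ``config.scene_duration_range``;
    consecutive scenes are separated by ``config.inter_scene_gap`` so
    that the 12 s post-scene window never overlaps the next scene.  The
    run length is derived from the schedule (last offset plus
    ``post_run_tail``, rounded up to a whole TR) unless
    ``config.run_duration`` is set, in which case a run too short to
    hold the schedule raises a sizing error naming the deficit.
    """
    if rng is None:
        rng = _rng_from(config.seed, 1)
    lo, hi = config.scene_duration_range
    durations = rng.uniform(lo, hi, size=config.n_scenes)
    onsets = np.empty(config.n_scenes)
    t = config.initial_rest
    for i, dur in enumerate(durations):
        onsets[i] = t
        t += dur + config.inter_scene_gap
    required = onsets[-1] + durations[-1] + config.post_run_tail
    if config.run_duration is None:
        run_duration = math.ceil(required / config.tr) * config.tr
    else:
        run_duration = float(config.run_duration)
        if run_duration < required - 1e-9:
            raise ValueError(
                f"run of {run_duration:.1f} s cannot hold {config.n_scenes} scenes "
                f"plus the {config.post_run_tail:.0f} s tail: "
                f"{required - run_duration:.1f} s short"
            )
    return SceneSchedule(
        onsets=onsets,
        durations=durations,
        scene_ids=np.arange(1, config.n_scenes + 1),
        run_duration=run_duration,
    )


def sample_diaries(
    schedule: SceneSchedule,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    participant_ids: list[str] | None = None,
    resample_zero: bool = True,
) -> DiaryLabels:
    """Sample each participant's diary outcome.

    Every scene independently becomes a flashback with probability
    ``config.intrusion_prob``.  With ``resample_zero`` (default),
    participants drawing zero flashbacks are redrawn — the analogue of
    excluding participants who report no intrusions; disable it to get
    unconditioned draws (used for calibration checks).
    """
    if rng is None:
        rng = _rng_from(config.seed, 2)
    if participant_ids is None:
        participant_ids = [f"sub-{i + 1:02d}" for i in range(config.n_participants)]
    p = config.intrusion_prob
    n_scenes = schedule.n_scenes
    draws = rng.random((len(participant_ids), n_scenes)) < p
    if resample_zero:
        for _ in range(10_000):
            empty = ~draws.any(axis=1)
            if not empty.any():
                break
            draws[empty] = rng.random((int(empty.sum()), n_scenes)) < p
        else:  # pragma: no cover - p in (0,1) makes this unreachable in practice
            raise RuntimeError("failed to resample zero-flashback participants")
    frame = pd.DataFrame(
        {
            "participant_id": np.repeat(participant_ids, n_scenes),
            "scene_id": np.tile(schedule.scene_ids, len(participant_ids)),
            "label": np.where(draws.reshape(-1), FLASHBACK, POTENTIAL),
        }
    )
    return DiaryLabels(frame)


def make_networks(
    config: SimulationConfig,
    n_networks: int = 39,
    n_predictive: int = 3,
    effect: float | tuple[float, float, float] = 2.0,
    baseline_amplitude: float = 10.0,
    blob_sigma_range: tuple[float, float] | None = None,
    max_overlap: float = 0.3,
    rng: np.random.Generator | None = None,
) -> tuple[NetworkSpec, ...]:
    """Build unit-norm Gaussian-blob spatial networks on the voxel grid.

    The first ``n_predictive`` networks carry the flashback effect
    (``effect`` in every window if given as a scalar); the rest have an
    all-zero effect triple.  Blob centres are rejection-sampled until no
    pair of maps has |dot product| above ``max_overlap`` — strongly
    overlapping maps would violate the spatial-independence assumption
    the decomposition relies on.
    """
    if rng is None:
        rng = _rng_from(config.seed, 3)
    if n_predictive > n_networks:
        raise ValueError("n_predictive cannot exceed n_networks")
    if blob_sigma_range is None:
        # blob size tracks the grid so maps stay separable on small grids
        m = min(config.grid_shape)
        blob_sigma_range = (0.15 * m, 0.25 * m)
    if np.isscalar(effect):
        effect_triple = (float(effect),) * 3
    else:
        effect_triple = tuple(float(e) for e in effect)
    grid = np.indices(config.grid_shape).reshape(3, -1).astype(float)
    flat_maps: list[np.ndarray] = []
    specs: list[NetworkSpec] = []
    for k in range(n_networks):
        for _attempt in range(1000):
            centre = np.array([rng.uniform(0, s - 1) for s in config.grid_shape])
            sigma = rng.uniform(*blob_sigma_range)
            d2 = ((grid - centre[:, None]) ** 2).sum(axis=0)
            flat = np.exp(-d2 / (2 * sigma**2))
            flat /= np.linalg.norm(flat)
            if all(abs(np.dot(flat, other)) < max_overlap for other in flat_maps):
                break
        else:
            raise RuntimeError("could not place linearly independent network maps")
        flat_maps.append(flat)
        specs.append(
            NetworkSpec(
                component_id=k,
                spatial_map=flat.reshape(config.grid_shape),
                baseline_amplitude=baseline_amplitude,
                flashback_effect=effect_triple if k < n_predictive else (0.0, 0.0, 0.0),
            )
        )
    return tuple(specs)


def _network_timecourse(
    network: NetworkSpec,
    schedule: SceneSchedule,
    flashback_scene_ids: np.ndarray,
    scene_amplitudes: np.ndarray,
    config: SimulationConfig,
    n_frames: int,
) -> np.ndarray:
    """Convolved neural amplitude time course of one network for one run."""
    onsets = list(schedule.onsets)
    durations = list(schedule.durations)
    amplitudes = list(scene_amplitudes)
    if network.is_predictive and len(flashback_scene_ids):
        fb_mask = np.isin(schedule.scene_ids, flashback_scene_ids)
        for onset, duration in zip(schedule.onsets[fb_mask], schedule.durations[fb_mask]):
            for window, eff in zip(SCENE_WINDOWS, network.flashback_effect):
                if eff == 0.0:
                    continue
                start, end = window.bounds(onset, duration)
                if end > start:
                    onsets.append(start)
                    durations.append(end - start)
                    amplitudes.append(eff)
    return convolve_events(
        onsets,
        durations,
        amplitudes,
        config.tr,
        n_frames,
        hrf_model=config.hrf_model,
        oversampling=config.hrf_oversampling,
    )


def simulate_participant_bold(
    schedule: SceneSchedule,
    labels: pd.Series | DiaryLabels,
    networks: tuple[NetworkSpec, ...] | list[NetworkSpec],
    config: SimulationConfig,
    participant_id: str = "sub-01",
    rng: np.random.Generator | None = None,
) -> BoldRun:
    """Simulate one participant's 4D run from the generative model.

    ``labels`` may be a scene_id → label Series or a :class:`DiaryLabels`
    (the participant's rows are selected).  Deterministic given the rng
    state / config seed.
    """
    if rng is None:
        rng = _rng_from(config.seed, hash(participant_id) % (2**31))
    if isinstance(labels, DiaryLabels):
        labels = labels.for_participant(participant_id)
    for net in networks:
        if net.spatial_map.shape != tuple(config.grid_shape):
            raise ValueError(
                f"network {net.component_id} map shape {net.spatial_map.shape} "
                f"does not match grid {tuple(config.grid_shape)}"
            )
    fb_ids = np.asarray(labels.index[labels == FLASHBACK])
    n_frames = _n_frames(schedule.run_duration, config.tr)
    tcs = np.empty((len(networks), n_frames))
    for k, net in enumerate(networks):
        jitter = rng.normal(0.0, config.amplitude_jitter, size=schedule.n_scenes)
        scene_amplitudes = net.baseline_amplitude + jitter
        tcs[k] = _network_timecourse(net, schedule, fb_ids, scene_amplitudes, config, n_frames)
    flat_maps = np.stack([net.flat_map for net in networks])  # (K, V)
    data = flat_maps.T @ tcs  # (V, T)
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)
    data4d = data.reshape(*config.grid_shape, n_frames)
    return BoldRun(participant_id=participant_id, data=data4d, tr=config.tr)


def simulate_study(
    config: SimulationConfig,
    networks: tuple[NetworkSpec, ...] | list[NetworkSpec] | None = None,
) -> Study:
    """Simulate a full cohort: schedule, diaries and one run per participant.

    All randomness derives from ``config.seed``; the same seed yields a
    bit-identical study.
    """
    if networks is None:
        networks = default_networks(config)
    schedule = make_scene_schedule(config)
    diaries = sample_diaries(schedule, config)
    runs = []
    for i, pid in enumerate([f"sub-{j + 1:02d}" for j in range(config.n_participants)]):
        rng = _rng_from(config.seed, 100 + i)
        runs.append(
            simulate_participant_bold(
                schedule, diaries, networks, config, participant_id=pid, rng=rng
            )
        )
    return Study(
        runs=tuple(runs),
        schedule=schedule,
        diaries=diaries,
        networks=tuple(networks),
        config=config,
    )


# --------------------------------------------------------------------------
# canonical study conditions
# --------------------------------------------------------------------------


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The canonical desk-scale study configuration."""
    return replace(SimulationConfig(seed=seed), **overrides) if overrides else SimulationConfig(
        seed=seed
    )


def default_networks(
    config: SimulationConfig, n_networks: int = 39, n_predictive: int = 3
) -> tuple[NetworkSpec, ...]:
    """39 networks, 3 predictive with effect 2 x the voxel noise SD.

    Each predictive network carries its effect in a *single* window
    (cycling initial6 → remainder → post12), emulating networks whose
    involvement in intrusive-memory formation is specific to a moment
    of the scene rather than sustained throughout.
    """
    networks = make_networks(
        config,
        n_networks=n_networks,
        n_predictive=n_predictive,
        effect=2.0 * config.noise_sd,
    )
    specific = []
    for net in networks:
        if net.is_predictive:
            triple = [0.0, 0.0, 0.0]
            triple[net.component_id % 3] = 2.0 * config.noise_sd
            net = replace(net, flashback_effect=tuple(triple))
        specific.append(net)
    return tuple(specific)


def default_study(seed: int = 0, **overrides) -> Study:
    """The canonical planted-effect study (35 participants, 39 networks)."""
    config = default_config(seed=seed, **overrides)
    return simulate_study(config, default_networks(config))


def null_study(seed: int = 0, **overrides) -> Study:
    """Same conditions but no flashback effect anywhere (negative control)."""
    config = default_config(seed=seed, **overrides)
    return simulate_study(config, default_networks(config, n_predictive=0))
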