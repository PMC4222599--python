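"""Group spatial ICA and dual-regression back-projection.

Temporal-concatenation group ICA: all participants' runs are stacked
along the time axis, rank-reduced by a truncated SVD, and unmixed by a
fixed-point ICA that maximises independence *over voxels*.  The
resulting spatial component maps describe regions of concurrent
activity across the whole cohort.  Stage-1 dual regression then
recovers, for each participant, a per-component activation time course
by regressing every acquired volume onto all spatial maps jointly.

Conventions (ICA is identifiable only up to sign/permutation): maps are
unit L2 norm, the largest-magnitude weight of each map is positive, and
components are ordered by descending explained variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.extmath import randomized_svd

from .simulate import BoldRun

__all__ = [
    "GroupDecomposition",
    "ComponentTimecourses",
    "ConcatenatedRuns",
    "IcaConvergenceError",
    "concatenate_runs",
    "fit_group_ica",
    "backproject_components",
    "match_components",
]


class IcaConvergenceError(RuntimeError):
    """Fixed-point ICA failed to reach tolerance; carries the iteration count."""

    def __init__(self, n_iter: int, max_iter: int):
        self.n_iter = n_iter
        self.max_iter = max_iter
        super().__init__(
            f"FastICA did not converge within {max_iter} iterations "
            f"(ran {n_iter}); the data may hold fewer independent sources "
            "than requested components"
        )


@dataclass(frozen=True)
class ConcatenatedRuns:
    """Temporally concatenated, block-normalized multi-participant data."""

    data: np.ndarray  # (total timepoints, voxels)
    block_slices: tuple[slice, ...]
    participant_ids: tuple[str, ...]
    grid_shape: tuple[int, int, int]

    def block(self, participant_id: str) -> np.ndarray:
        idx = self.participant_ids.index(participant_id)
        return self.data[self.block_slices[idx]]


@dataclass(frozen=True)
class GroupDecomposition:
    """Spatial component maps shared across participants, plus fit metadata."""

    spatial_maps: np.ndarray  # (n_components, voxels), unit-norm rows
    grid_shape: tuple[int, int, int] | None
    explained_variance: np.ndarray
    seed: int
    n_iter: int
    converged: bool

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.spatial_maps.shape[1]

    def maps_4d(self) -> np.ndarray:
        """Maps as a 4D array (x, y, z, component)."""
        if self.grid_shape is None:
            raise ValueError("decomposition carries no grid shape")
        return self.spatial_maps.T.reshape(*self.grid_shape, self.n_components)


@dataclass(frozen=True)
class ComponentTimecourses:
    """Per-participant activation time course of every group component."""

    participant_id: str
    values: np.ndarray  # (n_components, timepoints)
    tr: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("values must be components x timepoints")
        if not np.all(np.isfinite(values)):
            raise ValueError("time courses contain non-finite values")

    @property
    def n_components(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


def concatenate_runs(
    runs: list[BoldRun] | tuple[BoldRun, ...],
    mask: np.ndarray | None = None,
) -> ConcatenatedRuns:
    """Stack runs along time, normalizing each participant's block.

    Per block: each voxel's temporal mean is removed, then the whole
    block is divided by its pooled standard deviation so no participant
    dominates the group decomposition.  ``mask`` (3D boolean, optional)
    restricts the voxel set; by default all voxels are used.
    """
    if not runs:
        raise ValueError("no runs to concatenate")
    grid_shape = runs[0].grid_shape
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid_shape:
            raise ValueError("mask shape does not match the voxel grid")
        flat_mask = mask.reshape(-1)
    else:
        flat_mask = slice(None)
    for run in runs:
        if run.grid_shape != grid_shape:
            raise ValueError(
                f"participant {run.participant_id!r} has grid {run.grid_shape}, "
                f"expected {grid_shape}"
            )
    n_voxels = (
        int(np.count_nonzero(mask)) if mask is not None else int(np.prod(grid_shape))
    )
    total_time = sum(run.n_timepoints for run in runs)
    data = np.empty((total_time, n_voxels))
    slices = []
    start = 0
    for run in runs:
        stop = start + run.n_timepoints
        block = data[start:stop]
        np.copyto(block, run.flat()[:, flat_mask])
        block -= block.mean(axis=0, keepdims=True)
        scale = block.std()
        if scale > 0:
            block /= scale
        slices.append(slice(start, stop))
        start = stop
    return ConcatenatedRuns(
        data=data,
        block_slices=tuple(slices),
        participant_ids=tuple(run.participant_id for run in runs),
        grid_shape=grid_shape,
    )


def _fastica_once(reduced: np.ndarray, n_components: int, seed: int, max_iter: int, tol: float):
    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed) % (2**31),
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        maps = ica.fit_transform(reduced.T).T  # (k, voxels)
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    return maps, ica.n_iter_, converged


def fit_group_ica(
    concatenated: ConcatenatedRuns | np.ndarray,
    n_components: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    on_fail: str = "error",
) -> GroupDecomposition:
    """Fit the group spatial ICA on concatenated data.

    The timepoints x voxels matrix is reduced to ``n_components``
    dimensions by a randomized SVD and unmixed by FastICA with
    independence taken over voxels.  If the first fit does not reach
    ``tol``, one restart with a fixed derived seed is attempted; a
    second failure raises :class:`IcaConvergenceError` (``on_fail=
    "error"``) or keeps the last estimate with a warning (``"warn"`` —
    useful when deliberately over-specifying the component count).
    """
    if on_fail not in ("error", "warn"):
        raise ValueError("on_fail must be 'error' or 'warn'")
    if isinstance(concatenated, ConcatenatedRuns):
        X = concatenated.data
        grid_shape = concatenated.grid_shape
    else:
        X = np.asarray(concatenated, dtype=float)
        grid_shape = None
    if X.ndim != 2:
        raise ValueError("concatenated data must be 2D (timepoints x voxels)")
    n_time, n_voxels = X.shape
    if not (1 <= n_components <= min(n_time, n_voxels)):
        raise ValueError(
            f"n_components={n_components} must lie in [1, min(timepoints, voxels)"
            f"={min(n_time, n_voxels)}]"
        )
    mu = X.mean(axis=0)
    if np.abs(mu).max() > 1e-12:  # ConcatenatedRuns blocks are already demeaned
        X = X - mu
    U, S, Vt = randomized_svd(
        X, n_components=n_components, random_state=int(seed) % (2**31), n_iter=2
    )
    if S[0] > 0 and S[-1] < 1e-10 * S[0]:
        raise ValueError(
            f"n_components={n_components} exceeds the numerical rank of the data"
        )
    reduced = S[:, None] * Vt  # (k, voxels) spatial eigenmaps

    maps, n_iter, converged = _fastica_once(reduced, n_components, seed, max_iter, tol)
    if not converged:
        maps, n_iter, converged = _fastica_once(
            reduced, n_components, seed + 1, max_iter, tol
        )
    if not converged:
        if on_fail == "error":
            raise IcaConvergenceError(n_iter=n_iter, max_iter=max_iter)
        warnings.warn(
            f"group ICA did not converge in {n_iter} iterations; "
            "keeping the final estimate",
            ConvergenceWarning,
            stacklevel=2,
        )

    # sign/order conventions
    norms = np.linalg.norm(maps, axis=1)
    norms[norms == 0] = 1.0
    maps = maps / norms[:, None]
    peak = np.take_along_axis(
        maps, np.abs(maps).argmax(axis=1)[:, None], axis=1
    )[:, 0]
    maps = maps * np.where(peak < 0, -1.0, 1.0)[:, None]
    # order by the variance each component's time course explains, computed
    # in the rank-k representation (X ~= U S Vt): A = U S (Vt pinv(maps))
    mixing = (U * S) @ (Vt @ np.linalg.pinv(maps))  # (T, k)
    explained = mixing.var(axis=0)
    order = np.argsort(-explained, kind="stable")
    return GroupDecomposition(
        spatial_maps=maps[order],
        grid_shape=grid_shape,
        explained_variance=explained[order],
        seed=int(seed),
        n_iter=int(n_iter),
        converged=bool(converged),
    )


def backproject_components(
    decomposition: GroupDecomposition, run: BoldRun
) -> ComponentTimecourses:
    """Stage-1 dual regression of one run onto the group maps.

    Every volume is regressed on all spatial maps jointly (ordinary
    least squares); the coefficient series per component is that
    participant's activation time course.  Raises if the maps are
    collinear (singular design).
    """
    flat = run.flat()  # (T, V)
    if flat.shape[1] != decomposition.n_voxels:
        raise ValueError(
            f"run has {flat.shape[1]} voxels but the decomposition expects "
            f"{decomposition.n_voxels}"
        )
    design = decomposition.spatial_maps.T  # (V, k)
    coef, _, rank, _ = np.linalg.lstsq(design, flat.T, rcond=None)
    if rank < decomposition.n_components:
        raise np.linalg.LinAlgError(
            "spatial maps are collinear; back-projection design is singular"
        )
    return ComponentTimecourses(
        participant_id=run.participant_id, values=coef, tr=run.tr
    )


def match_components(
    true_maps: np.ndarray, estimated_maps: np.ndarray
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching of planted to estimated maps.

    Both inputs are (n_maps, voxels).  Pairs are assigned in descending
    absolute spatial correlation; returns ``(true_idx, est_idx, |r|)``
    triples, one per true map.  Used to resolve the ICA's permutation
    ambiguity against ground truth.
    """
    true_maps = np.asarray(true_maps, dtype=float)
    estimated_maps = np.asarray(estimated_maps, dtype=float)
    tz = (true_maps - true_maps.mean(axis=1, keepdims=True))
    ez = (estimated_maps - estimated_maps.mean(axis=1, keepdims=True))
    tz = tz / np.linalg.norm(tz, axis=1, keepdims=True)
    ez = ez / np.linalg.norm(ez, axis=1, keepdims=True)
    corr = np.abs(tz @ ez.T)
    pairs: list[tuple[int, int, float]] = []
    used_t: set[int] = set()
    used_e: set[int] = set()
    flat_order = np.argsort(-corr, axis=None, kind="stable")
    for flat_idx in flat_order:
        t, e = np.unravel_index(flat_idx, corr.shape)
        if t in used_t or e in used_e:
            continue
        pairs.append((int(t), int(e), float(corr[t, e])))
        used_t.add(int(t))
        used_e.add(int(e))
        if len(used_t) == corr.shape[0] or len(used_e) == corr.shape[1]:
            break
    pairs.sort(key=lambda p: p[0])
    return pairs
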