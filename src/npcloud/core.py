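"""Nearest-pair displacement clouds and iterative shift estimation.

The central primitive of the package: for every localization in a *moving*
set, find its nearest neighbor in a *reference* set within a small search
radius and record the vectorial displacement (moving − reference).  The
resulting "cloud" of displacements is centered on the translational shift
between the two sets; averaging its coordinates and iterating (shifting the
moving set by the running estimate and re-pairing) converges on the shift
even in the presence of heavy uncorrelated background, because each
iteration makes the radius-clipped background more symmetric about the
origin.

In 3D, candidate pairs are gated by a cylinder (lateral distance ≤ r_xy and
|Δz| ≤ r_z); among candidates, "nearest" minimizes the anisotropy-normalized
distance sqrt((Δxy/r_xy)² + (Δz/r_z)²) so that lateral and axial precisions
are treated consistently.  A plain-Euclidean alternative is switchable for
sensitivity checks.  Matching is one-directional and many-to-one; ties are
broken toward the lower reference record index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np
from scipy.spatial import cKDTree

from .io import EmptyInputError, LocalizationTable

__all__ = [
    "SearchRadii",
    "DisplacementCloud",
    "ShiftEstimate",
    "DimensionalityError",
    "InsufficientPairsError",
    "PointIndex",
    "pair_nearest",
    "pair_nearest_bruteforce",
    "cloud_mean",
    "estimate_shift_iterative",
    "DEFAULT_N_MIN",
    "DEFAULT_MAX_ITER",
]

#: Minimum pair count for a valid cloud mean.
DEFAULT_N_MIN = 10
#: Iteration cap for the converging estimator; typical convergence is <= 7.
DEFAULT_MAX_ITER = 20


class DimensionalityError(ValueError):
    """Moving and reference sets (or radii) have incompatible dimensions."""


class InsufficientPairsError(ValueError):
    """Too few nearest pairs to form a meaningful cloud mean."""

    def __init__(self, n_pairs: int, n_min: int):
        self.n_pairs = n_pairs
        self.n_min = n_min
        super().__init__(f"only {n_pairs} nearest pairs found (need >= {n_min})")


@dataclass(frozen=True)
class SearchRadii:
    """Search radii in nm: lateral ``r_xy`` and (3D only) axial ``r_z``."""

    r_xy: float = 50.0
    r_z: float = 100.0

    def __post_init__(self):
        if self.r_xy <= 0:
            raise ValueError("r_xy must be positive")
        if self.r_z <= 0:
            raise ValueError("r_z must be positive")


@dataclass(frozen=True)
class DisplacementCloud:
    """Nearest-pair displacements (moving − reference) within the radii."""

    displacements: np.ndarray   # (n_pairs, d) nm
    moving_index: np.ndarray    # (n_pairs,) indices into the moving set
    reference_index: np.ndarray # (n_pairs,) indices into the reference set
    n_moving: int
    radii: SearchRadii

    @property
    def n_pairs(self) -> int:
        return self.displacements.shape[0]

    @property
    def ndim(self) -> int:
        return self.displacements.shape[1]


@dataclass(frozen=True)
class ShiftEstimate:
    """A converged translational shift (moving − reference sense)."""

    shift: np.ndarray            # (d,) nm — sum of retained iteration steps
    iterations: List[np.ndarray] # per-iteration stepwise shifts
    converged: bool
    n_pairs_final: int


class PointIndex:
    """Reusable spatial index over a fixed reference point set.

    The sequential drift pipeline pairs every segment against the same
    reference, so the k-d tree is built once here and queried many times
    instead of being rebuilt per pairing.
    """

    def __init__(self, points: Union[LocalizationTable, np.ndarray]):
        self.coords = _coords(points)
        self._trees: dict = {}

    @property
    def ndim(self) -> int:
        return self.coords.shape[1]

    def tree(self, scale=None) -> cKDTree:
        key = None if scale is None else tuple(np.asarray(scale).tolist())
        if key not in self._trees:
            pts = self.coords if scale is None else self.coords / np.asarray(scale)
            self._trees[key] = cKDTree(pts)
        return self._trees[key]


def _coords(obj: Union[LocalizationTable, np.ndarray]) -> np.ndarray:
    if isinstance(obj, PointIndex):
        return obj.coords
    if isinstance(obj, LocalizationTable):
        return obj.coords
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2 or arr.shape[1] not in (2, 3):
        raise DimensionalityError(f"expected (n, 2) or (n, 3) coordinates, got {arr.shape}")
    return arr


def _check_inputs(moving, reference) -> tuple:
    a, b = _coords(moving), _coords(reference)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise EmptyInputError("pairing requires non-empty moving and reference sets")
    if a.shape[1] != b.shape[1]:
        raise DimensionalityError(
            f"moving is {a.shape[1]}D but reference is {b.shape[1]}D"
        )
    return a, b


def pair_nearest(
    moving: Union[LocalizationTable, np.ndarray],
    reference: Union[LocalizationTable, np.ndarray],
    radii: SearchRadii = SearchRadii(),
    metric: str = "normalized",
) -> DisplacementCloud:
    """Build the nearest-pair displacement cloud of *moving* vs *reference*.

    Each moving localization is matched to its nearest reference
    localization within the search radii (one-directional, many-to-one).
    Frame indices are ignored at this level.  ``metric`` selects the 3D
    nearest-candidate criterion: ``"normalized"`` (radius-scaled, default)
    or ``"euclidean"``; both use the same cylindrical gating.
    """
    ref = reference if isinstance(reference, PointIndex) else PointIndex(reference)
    a, b = _check_inputs(moving, ref)
    d = a.shape[1]
    if d == 2:
        dist, idx = ref.tree().query(a, k=1, distance_upper_bound=radii.r_xy)
        matched = np.isfinite(dist)
        mov_idx = np.flatnonzero(matched)
        ref_idx = idx[matched]
    else:
        mov_idx, ref_idx = _pair_nearest_3d(a, ref, radii, metric)
    disp = a[mov_idx] - b[ref_idx] if mov_idx.size else np.empty((0, d))
    return DisplacementCloud(
        displacements=disp,
        moving_index=mov_idx.astype(np.int64),
        reference_index=ref_idx.astype(np.int64),
        n_moving=a.shape[0],
        radii=radii,
    )


def _pair_nearest_3d(a, ref: PointIndex, radii: SearchRadii, metric: str):
    if metric not in ("normalized", "euclidean"):
        raise ValueError(f"unknown metric '{metric}'")
    b = ref.coords
    scale = np.array([radii.r_xy, radii.r_xy, radii.r_z])
    tree = ref.tree(scale)
    # The cylindrical gate is contained in the normalized ball of radius √2.
    lists = tree.query_ball_point(a / scale, np.sqrt(2.0) * (1 + 1e-12))
    counts = np.fromiter((len(l) for l in lists), dtype=np.int64, count=len(lists))
    if counts.sum() == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    flat_ref = np.concatenate([np.asarray(l, dtype=np.int64) for l in lists if l])
    flat_mov = np.repeat(np.arange(a.shape[0]), counts)
    delta = a[flat_mov] - b[flat_ref]
    dxy = np.hypot(delta[:, 0], delta[:, 1])
    dz = np.abs(delta[:, 2])
    inside = (dxy <= radii.r_xy) & (dz <= radii.r_z)
    if metric == "normalized":
        score = np.sqrt((dxy / radii.r_xy) ** 2 + (dz / radii.r_z) ** 2)
    else:
        score = np.sqrt(dxy**2 + dz**2)
    score = np.where(inside, score, np.inf)
    # Group-wise argmin over candidates of each moving point.  Candidate
    # lists from query_ball_point are index-sorted, so the first minimum in
    # flat order realizes the lowest-reference-index tie-break.
    offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
    nonempty = counts > 0
    gmin = np.full(a.shape[0], np.inf)
    if nonempty.any():
        gmin[nonempty] = np.minimum.reduceat(score, offsets[nonempty])
    is_best = np.isfinite(score) & (score == gmin[flat_mov])
    mov_best = flat_mov[is_best]
    ref_best = flat_ref[is_best]
    # first occurrence per moving index = lowest reference index among ties
    uniq_mov, first = np.unique(mov_best, return_index=True)
    return uniq_mov, ref_best[first]


def pair_nearest_bruteforce(
    moving: Union[LocalizationTable, np.ndarray],
    reference: Union[LocalizationTable, np.ndarray],
    radii: SearchRadii = SearchRadii(),
    metric: str = "normalized",
) -> DisplacementCloud:
    """Exhaustive all-pairs version of :func:`pair_nearest` (test oracle).

    Identical contract; O(n·m) time and memory, intended for small inputs.
    """
    a, b = _check_inputs(moving, reference)
    d = a.shape[1]
    mov_idx, ref_idx = [], []
    for i in range(a.shape[0]):
        delta = a[i] - b
        if d == 2:
            dist = np.hypot(delta[:, 0], delta[:, 1])
            inside = dist <= radii.r_xy
            score = dist
        else:
            dxy = np.hypot(delta[:, 0], delta[:, 1])
            dz = np.abs(delta[:, 2])
            inside = (dxy <= radii.r_xy) & (dz <= radii.r_z)
            if metric == "normalized":
                score = np.sqrt((dxy / radii.r_xy) ** 2 + (dz / radii.r_z) ** 2)
            elif metric == "euclidean":
                score = np.sqrt(dxy**2 + dz**2)
            else:
                raise ValueError(f"unknown metric '{metric}'")
        score = np.where(inside, score, np.inf)
        j = int(np.argmin(score))  # argmin takes the first (lowest) index on ties
        if np.isfinite(score[j]):
            mov_idx.append(i)
            ref_idx.append(j)
    mov_idx = np.asarray(mov_idx, dtype=np.int64)
    ref_idx = np.asarray(ref_idx, dtype=np.int64)
    disp = a[mov_idx] - b[ref_idx] if mov_idx.size else np.empty((0, d))
    return DisplacementCloud(disp, mov_idx, ref_idx, a.shape[0], radii)


def cloud_mean(cloud: DisplacementCloud, n_min: int = DEFAULT_N_MIN) -> np.ndarray:
    """Component-wise arithmetic mean of the cloud's displacements.

    Raises :class:`InsufficientPairsError` when fewer than ``n_min`` pairs
    are available — below that the mean is dominated by noise.
    """
    if cloud.n_pairs < n_min:
        raise InsufficientPairsError(cloud.n_pairs, n_min)
    return cloud.displacements.mean(axis=0)


def estimate_shift_iterative(
    moving: Union[LocalizationTable, np.ndarray],
    reference: Union[LocalizationTable, np.ndarray],
    radii: SearchRadii = SearchRadii(),
    max_iter: int = DEFAULT_MAX_ITER,
    n_min: int = DEFAULT_N_MIN,
    metric: str = "normalized",
) -> ShiftEstimate:
    """Iteratively converge on the shift of *moving* relative to *reference*.

    Each iteration shifts the moving set back by the accumulated estimate,
    re-pairs, and averages the new cloud.  Iteration stops when the cloud
    mean no longer moves closer to the origin than in the previous
    iteration; the final non-improving step is discarded.  In 3D the
    lateral (xy-norm) and axial (|z|) criteria are tracked independently
    and both must stall, with cloud centers averaged separately for xy and
    z each iteration (one joint 3D pairing per iteration).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    ref = reference if isinstance(reference, PointIndex) else PointIndex(reference)
    a, _ = _check_inputs(moving, ref)
    d = a.shape[1]
    acc = np.zeros(d)
    steps: List[np.ndarray] = []
    converged = False
    prev_xy = np.inf
    prev_z = np.inf
    n_pairs_final = 0
    for _ in range(max_iter):
        cloud = pair_nearest(a - acc, ref, radii, metric=metric)
        step = cloud_mean(cloud, n_min)
        if d == 2:
            mag = float(np.linalg.norm(step))
            if not mag < prev_xy:
                converged = True
                break
            prev_xy = mag
        else:
            mag_xy = float(np.linalg.norm(step[:2]))
            mag_z = float(abs(step[2]))
            improved_xy = mag_xy < prev_xy
            improved_z = mag_z < prev_z
            if not (improved_xy or improved_z):
                converged = True
                break
            if improved_xy:
                prev_xy = mag_xy
            if improved_z:
                prev_z = mag_z
        acc = acc + step
        steps.append(step)
        n_pairs_final = cloud.n_pairs
    return ShiftEstimate(
        shift=acc, iterations=steps, converged=converged, n_pairs_final=n_pairs_final
    )
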