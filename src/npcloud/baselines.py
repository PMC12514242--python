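"""Grid-binned cross-correlation baselines: DCC and RCC.

DCC (direct cross-correlation) renders each frame segment as a 2D
localization histogram on a fixed grid (default 15 nm) and estimates each
segment's shift versus the first segment from the peak of their FFT
cross-correlation, with 3×3 intensity-centroid sub-pixel refinement.  RCC
(redundant cross-correlation) estimates shifts for *all* segment pairs and
solves the over-determined system d_ij ≈ r_j − r_i by least squares with a
single outlier-rejection re-solve.  Both exist for head-to-head comparison
against the nearest-pair methods; they are 2D only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Tuple, Union

import numpy as np
from scipy.signal import fftconvolve

from .io import DriftTrace, EmptyInputError, LocalizationTable
from .pipeline import SegmentSpec, _segment_indices, interpolate_drift, segment_frames

__all__ = [
    "BinnedImage",
    "UndefinedShiftError",
    "bin_localizations",
    "xcorr_shift",
    "dcc_drift",
    "rcc_drift",
    "pairwise_correlation_count",
    "single_reference_correlation_count",
]

DEFAULT_GRID_SIZE = 15.0   # nm
DEFAULT_MAX_LAG = 1000.0   # nm; restricts peak search to plausible drifts
DEFAULT_OUTLIER_THRESHOLD = 30.0  # nm (2 grid cells) for RCC rejection


class UndefinedShiftError(ValueError):
    """Cross-correlation cannot produce a shift (e.g. an all-zero image)."""


@dataclass(frozen=True)
class BinnedImage:
    """2D localization histogram: ``counts[iy, ix]`` on a square grid."""

    counts: np.ndarray       # (rows, cols) int
    grid_size: float         # nm
    origin: Tuple[float, float]  # (x0, y0) nm of the grid corner

    @property
    def shape(self) -> Tuple[int, int]:
        return self.counts.shape


def bin_localizations(
    table: Union[LocalizationTable, np.ndarray],
    grid_size: float = DEFAULT_GRID_SIZE,
    bounds: Optional[Tuple[Tuple[float, float], Tuple[float, float]]] = None,
) -> BinnedImage:
    """Histogram (x, y) positions onto a square grid.

    Bins are half-open ``[edge, edge + grid_size)``; localizations outside
    ``bounds`` (``((x0, x1), (y0, y1))``, default the data extent) are
    dropped.  An empty subset yields an all-zero image when bounds are
    supplied.
    """
    if grid_size <= 0:
        raise ValueError("grid_size must be positive")
    xy = table.coords[:, :2] if isinstance(table, LocalizationTable) else np.asarray(table, float)
    if bounds is None:
        if xy.shape[0] == 0:
            raise EmptyInputError("cannot infer bounds from an empty table")
        bounds = (
            (xy[:, 0].min(), xy[:, 0].max()),
            (xy[:, 1].min(), xy[:, 1].max()),
        )
    (x0, x1), (y0, y1) = bounds
    ncols = int(np.floor((x1 - x0) / grid_size)) + 1
    nrows = int(np.floor((y1 - y0) / grid_size)) + 1
    counts = np.zeros((nrows, ncols), dtype=np.int64)
    if xy.shape[0]:
        ix = np.floor((xy[:, 0] - x0) / grid_size).astype(np.int64)
        iy = np.floor((xy[:, 1] - y0) / grid_size).astype(np.int64)
        keep = (ix >= 0) & (ix < ncols) & (iy >= 0) & (iy < nrows)
        np.add.at(counts, (iy[keep], ix[keep]), 1)
    return BinnedImage(counts=counts, grid_size=float(grid_size), origin=(float(x0), float(y0)))


def xcorr_shift(
    a: BinnedImage, b: BinnedImage, max_lag: float = DEFAULT_MAX_LAG
) -> np.ndarray:
    """Shift of image *a* relative to *b* (nm) from their cross-correlation.

    Linear (zero-padded) FFT correlation; the integer peak within the
    ±``max_lag`` window is refined by the intensity centroid of its 3×3
    neighborhood.  Sign convention matches the nearest-pair estimator:
    positive shift means *a*'s content sits at larger coordinates than
    *b*'s.
    """
    if a.grid_size != b.grid_size or a.shape != b.shape or a.origin != b.origin:
        raise ValueError("images must share grid size, shape and origin")
    if not a.counts.any() or not b.counts.any():
        raise UndefinedShiftError("cross-correlation of an all-zero image")
    fa = a.counts.astype(float)
    fb = b.counts.astype(float)
    corr = fftconvolve(fa, fb[::-1, ::-1], mode="full")
    nrows, ncols = a.shape
    lag_y = np.arange(-(nrows - 1), nrows)
    lag_x = np.arange(-(ncols - 1), ncols)
    max_bins = max_lag / a.grid_size
    masked = corr.copy()
    masked[np.abs(lag_y) > max_bins, :] = -np.inf
    masked[:, np.abs(lag_x) > max_bins] = -np.inf
    peak_flat = int(np.argmax(masked))
    py, px = np.unravel_index(peak_flat, corr.shape)
    if not np.isfinite(masked[py, px]) or corr[py, px] <= 0:
        raise UndefinedShiftError("no positive correlation peak within the lag window")
    # 3x3 intensity centroid around the integer peak (clipped at borders)
    y0, y1 = max(py - 1, 0), min(py + 2, corr.shape[0])
    x0, x1 = max(px - 1, 0), min(px + 2, corr.shape[1])
    patch = np.clip(corr[y0:y1, x0:x1], 0, None)
    total = patch.sum()
    if total > 0:
        yy, xx = np.mgrid[y0:y1, x0:x1]
        cy = (patch * yy).sum() / total - py
        cx = (patch * xx).sum() / total - px
    else:  # pragma: no cover - peak>0 guarantees total>0
        cy = cx = 0.0
    shift_x = (lag_x[px] + cx) * a.grid_size
    shift_y = (lag_y[py] + cy) * a.grid_size
    return np.array([shift_x, shift_y])


def _binned_segments(table: LocalizationTable, spec: SegmentSpec, grid_size: float):
    if table.is_3d:
        raise ValueError("grid-binned correlation baselines are 2D only")
    xy = table.coords
    bounds = (
        (xy[:, 0].min(), xy[:, 0].max()),
        (xy[:, 1].min(), xy[:, 1].max()),
    )
    seg_idx = _segment_indices(table.frame, spec)
    return [bin_localizations(xy[idx], grid_size, bounds) for idx in seg_idx]


def dcc_drift(
    table: LocalizationTable,
    L: int,
    grid_size: float = DEFAULT_GRID_SIZE,
    max_lag: float = DEFAULT_MAX_LAG,
) -> DriftTrace:
    """Single-referenced grid-binned cross-correlation drift estimation.

    Every segment's histogram image is correlated with the first
    segment's; a segment with an undefined shift inherits the previous
    segment's drift with a warning.
    """
    spec = segment_frames(table, L)
    images = _binned_segments(table, spec, grid_size)
    drift = np.zeros((spec.n_segments, 2))
    for k in range(1, spec.n_segments):
        try:
            drift[k] = xcorr_shift(images[k], images[0], max_lag=max_lag)
        except UndefinedShiftError as exc:
            warnings.warn(f"segment {k + 1}: {exc}; inheriting prior drift")
            drift[k] = drift[k - 1]
    anchors = spec.anchor_frames
    return DriftTrace(
        anchor_frames=anchors,
        segment_drift=drift,
        frame_drift=interpolate_drift(anchors, drift, table.max_frame),
    )


def pairwise_correlation_count(n_segments: int) -> int:
    """Number of segment-pair correlations the redundant approach computes."""
    return n_segments * (n_segments - 1) // 2


def single_reference_correlation_count(n_segments: int) -> int:
    """Number of correlations the single-referenced approach computes."""
    return n_segments - 1


def rcc_drift(
    table: LocalizationTable,
    L: int,
    grid_size: float = DEFAULT_GRID_SIZE,
    max_lag: float = DEFAULT_MAX_LAG,
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD,
) -> DriftTrace:
    """Redundant cross-correlation drift estimation.

    Shifts d_ij are measured for all segment pairs i<j and the per-segment
    drifts r_k (r_1 = 0) solved by least squares on d_ij ≈ r_j − r_i.
    Pairs whose post-fit residual norm exceeds ``outlier_threshold`` are
    dropped and the system re-solved once.  Quadratic in the number of
    segments — a minimal comparison baseline, not a production method.
    """
    spec = segment_frames(table, L)
    S = spec.n_segments
    if S < 2:
        raise ValueError("redundant correlation needs at least 2 segments")
    if S > 200:
        warnings.warn(
            f"{S} segments -> {pairwise_correlation_count(S)} pairwise "
            "correlations; this is quadratic and may be very slow"
        )
    images = _binned_segments(table, spec, grid_size)
    pairs, d_obs = [], []
    for i, j in combinations(range(S), 2):
        try:
            d_obs.append(xcorr_shift(images[j], images[i], max_lag=max_lag))
            pairs.append((i, j))
        except UndefinedShiftError:
            continue
    if not pairs:
        raise UndefinedShiftError("no valid pairwise correlations")
    d_obs = np.asarray(d_obs)

    def _solve(pair_list, obs):
        A = np.zeros((len(pair_list), S - 1))
        for row, (i, j) in enumerate(pair_list):
            if j > 0:
                A[row, j - 1] += 1.0
            if i > 0:
                A[row, i - 1] -= 1.0
        if np.linalg.matrix_rank(A) < S - 1:
            raise np.linalg.LinAlgError(
                "rank-deficient redundant system after outlier removal"
            )
        sol, *_ = np.linalg.lstsq(A, obs, rcond=None)
        return np.vstack([np.zeros(2), sol]), A

    r, A = _solve(pairs, d_obs)
    residual = d_obs - A @ r[1:]
    keep = np.linalg.norm(residual, axis=1) <= outlier_threshold
    if not keep.all() and keep.any():
        r, _ = _solve([p for p, k in zip(pairs, keep) if k], d_obs[keep])
    anchors = spec.anchor_frames
    return DriftTrace(
        anchor_frames=anchors,
        segment_drift=r,
        frame_drift=interpolate_drift(anchors, r, table.max_frame),
    )
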