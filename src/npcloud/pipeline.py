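"""Drift-correction workflows: segmentation, sequential nearest-pair-cloud
estimation, interpolation, correction, and the two-pass resampled-reference
variant.

The single-pass workflow splits the acquisition into fixed-length frame
segments, takes the first segment as the spatial reference, and walks the
remaining segments in order.  Each segment is pre-shifted by the drift
already estimated for the previous segment, so the residual shift versus
the reference fits comfortably inside a small (~50 nm) search radius; the
residual is estimated with the iterative cloud estimator and added back.
Because every segment is correlated with the *first* segment (never the
previous one), estimation errors do not accumulate along the acquisition.

The two-pass (resampled-reference) variant re-estimates every segment
against a feature-rich reference built by evenly subsampling the
first-pass-corrected dataset to ~12× the first segment's localization
count, which captures structure the stochastic first segment misses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import (
    DEFAULT_MAX_ITER,
    DEFAULT_N_MIN,
    InsufficientPairsError,
    SearchRadii,
    estimate_shift_iterative,
)
from .io import DriftTrace, EmptyInputError, LocalizationTable

__all__ = [
    "SegmentSpec",
    "RRConfig",
    "segment_frames",
    "npcloud_drift",
    "rr_npcloud_drift",
    "interpolate_drift",
    "apply_drift",
    "resample_reference",
]


@dataclass(frozen=True)
class SegmentSpec:
    """Fixed-length tiling of frames 1..max_frame into segments."""

    segment_length: int
    bounds: Tuple[Tuple[int, int], ...]  # 1-based inclusive [first, last]

    @property
    def n_segments(self) -> int:
        return len(self.bounds)

    @property
    def anchor_frames(self) -> np.ndarray:
        """Midpoint frame of each segment (round-half-up)."""
        return np.array(
            [int(np.floor((f + l) / 2 + 0.5)) for f, l in self.bounds], dtype=np.int64
        )


@dataclass(frozen=True)
class RRConfig:
    """Second-pass configuration: reference size as a multiple of the
    first segment's localization count (default 12)."""

    resample_factor: float = 12.0

    def __post_init__(self):
        if self.resample_factor < 1:
            raise ValueError("resample_factor must be >= 1")


def _segment_bounds(max_frame: int, L: int) -> Tuple[Tuple[int, int], ...]:
    if L < 1:
        raise ValueError("segment length must be >= 1")
    if L > max_frame:
        warnings.warn(
            f"segment length {L} exceeds max frame {max_frame}: "
            "single segment, drift correction is vacuous",
            stacklevel=3,
        )
        return ((1, max_frame),)
    starts = list(range(1, max_frame + 1, L))
    bounds = [(s, min(s + L - 1, max_frame)) for s in starts]
    # A trailing remainder shorter than L/2 is merged into the previous
    # segment to keep per-segment statistics roughly uniform.
    if len(bounds) > 1:
        first, last = bounds[-1]
        if (last - first + 1) < L / 2:
            bounds[-2] = (bounds[-2][0], last)
            bounds.pop()
    return tuple(bounds)


def segment_frames(table: Union[LocalizationTable, int], L: int) -> SegmentSpec:
    """Tile the acquisition into consecutive L-frame segments.

    ``table`` may be a LocalizationTable (its max frame is used) or the
    max frame index itself.
    """
    max_frame = table if isinstance(table, (int, np.integer)) else table.max_frame
    return SegmentSpec(segment_length=int(L), bounds=_segment_bounds(int(max_frame), int(L)))


def _segment_indices(frame: np.ndarray, spec: SegmentSpec) -> List[np.ndarray]:
    order = np.argsort(frame, kind="stable")
    sorted_frames = frame[order]
    out = []
    for first, last in spec.bounds:
        lo = np.searchsorted(sorted_frames, first, side="left")
        hi = np.searchsorted(sorted_frames, last, side="right")
        out.append(order[lo:hi])
    return out


def interpolate_drift(
    anchor_frames: Sequence[int], segment_drift: np.ndarray, max_frame: int
) -> np.ndarray:
    """Linearly interpolate per-segment drift to every frame.

    Constant extrapolation before the first and after the last anchor.
    Returns an (max_frame, d) array whose row t-1 is the drift of frame t.
    """
    anchors = np.asarray(anchor_frames, dtype=float)
    seg = np.atleast_2d(np.asarray(segment_drift, dtype=float))
    if anchors.size == 0:
        raise EmptyInputError("at least one anchor is required")
    frames = np.arange(1, max_frame + 1, dtype=float)
    return np.column_stack(
        [np.interp(frames, anchors, seg[:, j]) for j in range(seg.shape[1])]
    )


def apply_drift(
    table: LocalizationTable, drift: Union[DriftTrace, np.ndarray]
) -> LocalizationTable:
    """Subtract the per-frame drift from each localization's position."""
    frame_drift = drift.frame_drift if isinstance(drift, DriftTrace) else np.atleast_2d(
        np.asarray(drift, dtype=float)
    )
    if frame_drift.shape[1] != table.ndim:
        raise ValueError(
            f"drift is {frame_drift.shape[1]}D but table is {table.ndim}D"
        )
    if table.n and table.max_frame > frame_drift.shape[0]:
        raise ValueError(
            f"drift covers {frame_drift.shape[0]} frames but table reaches "
            f"frame {table.max_frame}"
        )
    return table.with_coords(table.coords - frame_drift[table.frame - 1])


def _estimate_segments(
    coords: np.ndarray,
    seg_idx: List[np.ndarray],
    reference: np.ndarray,
    init_drift: np.ndarray,
    sequential: bool,
    radii: SearchRadii,
    max_iter: int,
    n_min: int,
    metric: str,
    start: int = 1,
) -> np.ndarray:
    """Shared segment loop.  ``sequential=True`` chains the pre-shift from
    the previous segment's estimate (first pass); otherwise each segment is
    initialized from ``init_drift`` for that same segment (second pass)."""
    from .core import PointIndex

    reference = PointIndex(reference)  # build the reference tree once
    S = len(seg_idx)
    d = coords.shape[1]
    drift = np.array(init_drift, dtype=float, copy=True)
    for k in range(start, S):
        pre = drift[k - 1] if sequential else init_drift[k]
        seg = coords[seg_idx[k]]
        if seg.shape[0] == 0:
            warnings.warn(f"segment {k + 1} is empty; inheriting prior drift")
            drift[k] = drift[k - 1] if sequential else init_drift[k]
            continue
        try:
            est = estimate_shift_iterative(
                seg - pre, reference, radii, max_iter=max_iter, n_min=n_min, metric=metric
            )
            drift[k] = pre + est.shift
        except InsufficientPairsError as exc:
            warnings.warn(
                f"segment {k + 1}: {exc}; inheriting prior drift", stacklevel=2
            )
            drift[k] = drift[k - 1] if sequential else init_drift[k]
    return drift


def npcloud_drift(
    table: LocalizationTable,
    L: int,
    radii: SearchRadii = SearchRadii(),
    max_iter: int = DEFAULT_MAX_ITER,
    n_min: int = DEFAULT_N_MIN,
    metric: str = "normalized",
) -> DriftTrace:
    """Single-pass nearest-pair-cloud drift estimation.

    Segment 1 is the reference with zero drift; each later segment is
    pre-shifted by the previous segment's drift and its residual shift
    versus segment 1 is estimated iteratively.  Per-frame drift follows by
    linear interpolation between segment midpoints.
    """
    if table.n == 0:
        raise EmptyInputError("cannot estimate drift from an empty table")
    spec = segment_frames(table, L)
    coords = table.coords
    seg_idx = _segment_indices(table.frame, spec)
    reference = coords[seg_idx[0]]
    if reference.shape[0] == 0:
        raise EmptyInputError("reference segment contains no localizations")
    drift = _estimate_segments(
        coords,
        seg_idx,
        reference,
        init_drift=np.zeros((spec.n_segments, coords.shape[1])),
        sequential=True,
        radii=radii,
        max_iter=max_iter,
        n_min=n_min,
        metric=metric,
    )
    anchors = spec.anchor_frames
    return DriftTrace(
        anchor_frames=anchors,
        segment_drift=drift,
        frame_drift=interpolate_drift(anchors, drift, table.max_frame),
    )


def resample_reference(
    corrected: LocalizationTable,
    spec: SegmentSpec,
    cfg: RRConfig = RRConfig(),
) -> LocalizationTable:
    """Evenly subsample a corrected dataset into a feature-rich reference.

    Localizations ordered by frame are taken with a constant stride so the
    output count approximates ``resample_factor`` × (first-segment count),
    capped at the full dataset; the result spans all frames uniformly.
    The stride starts at index 0, keeping the operation deterministic.
    """
    if corrected.n == 0:
        raise EmptyInputError("cannot resample an empty table")
    order = np.argsort(corrected.frame, kind="stable")
    first, last = spec.bounds[0]
    n_seg1 = int(np.count_nonzero((corrected.frame >= first) & (corrected.frame <= last)))
    target = int(round(cfg.resample_factor * max(n_seg1, 1)))
    target = min(max(target, 1), corrected.n)
    stride = max(1, int(round(corrected.n / target)))
    return corrected.select(order[::stride])


def rr_npcloud_drift(
    table: LocalizationTable,
    L: int,
    radii: SearchRadii = SearchRadii(),
    cfg: RRConfig = RRConfig(),
    max_iter: int = DEFAULT_MAX_ITER,
    n_min: int = DEFAULT_N_MIN,
    metric: str = "normalized",
) -> DriftTrace:
    """Two-pass resampled-reference drift estimation.

    Pass 1 is :func:`npcloud_drift`.  Its per-frame drift corrects the
    dataset, which is evenly subsampled into the enlarged reference; pass 2
    then re-estimates every segment of the *original* data, pre-shifted by
    its pass-1 drift, against that reference.  The pass-2 residual of the
    reference segment is subtracted from all segments so the reference
    anchoring (zero drift for segment 1) is preserved exactly.
    """
    pass1 = npcloud_drift(table, L, radii, max_iter=max_iter, n_min=n_min, metric=metric)
    spec = segment_frames(table, L)
    corrected = apply_drift(table, pass1)
    ref_table = resample_reference(corrected, spec, cfg)
    coords = table.coords
    seg_idx = _segment_indices(table.frame, spec)
    drift = _estimate_segments(
        coords,
        seg_idx,
        ref_table.coords,
        init_drift=pass1.segment_drift,
        sequential=False,
        radii=radii,
        max_iter=max_iter,
        n_min=n_min,
        metric=metric,
        start=0,
    )
    drift = drift - drift[0]
    anchors = spec.anchor_frames
    return DriftTrace(
        anchor_frames=anchors,
        segment_drift=drift,
        frame_drift=interpolate_drift(anchors, drift, table.max_frame),
    )
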