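"""Localization tables, drift traces, and their delimited-text I/O.

Conventions used throughout the package
---------------------------------------
* Coordinates are continuous values in nanometres; no rounding or binning
  happens at I/O time.
* Frames are 1-based acquisition indices (camera convention).
* The y axis follows the camera convention (increasing downward); no sign
  flip is applied on read or write — flipping is a display concern.
* A table is either uniformly 2D (x, y) or uniformly 3D (x, y, z).

The default CSV dialect is comma-separated with a header row and columns
``x[nm], y[nm]`` (optionally ``z[nm]``) and ``frame``.  SMLM exports vary
wildly, so :class:`Dialect` lets callers remap arbitrary column names and
supply a pixel→nm scale for lateral coordinates stored in camera pixels.
The pixel scale applies to x and y only: z columns in SMLM exports are
conventionally already calibrated in nm.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "LocalizationError",
    "FormatError",
    "EmptyInputError",
    "LocalizationTable",
    "DriftTrace",
    "Dialect",
    "DEFAULT_DIALECT",
    "read_localizations",
    "write_localizations",
    "write_drift_trace",
    "read_drift_trace",
]


class LocalizationError(ValueError):
    """Base class for localization-data errors."""


class FormatError(LocalizationError):
    """A file or table does not conform to the expected schema."""


class EmptyInputError(LocalizationError):
    """An operation that needs localizations received none."""


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise FormatError(f"non-finite values in column '{name}'")
    return arr


@dataclass(frozen=True)
class LocalizationTable:
    """A set of single-molecule localizations.

    Parameters
    ----------
    x, y : array of float
        Lateral coordinates in nm.
    frame : array of int
        1-based acquisition frame index per localization.
    z : array of float, optional
        Axial coordinate in nm.  Present iff the table is 3D.
    """

    x: np.ndarray
    y: np.ndarray
    frame: np.ndarray
    z: Optional[np.ndarray] = None

    def __post_init__(self):
        x = _as_float_array(self.x, "x")
        y = _as_float_array(self.y, "y")
        frame = np.asarray(self.frame).ravel()
        if frame.size and not np.issubdtype(frame.dtype, np.integer):
            f = np.asarray(frame, dtype=float)
            if not np.all(np.isfinite(f)) or not np.all(f == np.round(f)):
                raise FormatError("frame indices must be integers")
            frame = f.astype(np.int64)
        else:
            frame = frame.astype(np.int64, copy=False)
        z = None if self.z is None else _as_float_array(self.z, "z")
        n = x.size
        sizes = {y.size, frame.size} | ({z.size} if z is not None else set())
        if sizes != {n}:
            raise FormatError("x, y, z, frame must have equal lengths")
        if n and frame.min() < 1:
            raise FormatError("frame indices must be >= 1")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "frame", frame)
        object.__setattr__(self, "z", z)

    @property
    def n(self) -> int:
        return self.x.size

    def __len__(self) -> int:
        return self.n

    @property
    def is_3d(self) -> bool:
        return self.z is not None

    @property
    def ndim(self) -> int:
        return 3 if self.is_3d else 2

    @property
    def coords(self) -> np.ndarray:
        """Coordinates as an (n, 2) or (n, 3) float array in nm."""
        cols = [self.x, self.y] + ([self.z] if self.is_3d else [])
        return np.column_stack(cols) if self.n else np.empty((0, self.ndim))

    def with_coords(self, coords: np.ndarray) -> "LocalizationTable":
        """Return a copy with the same frames but new coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n, self.ndim):
            raise FormatError(
                f"coords shape {coords.shape} does not match table "
                f"({self.n}, {self.ndim})"
            )
        z = coords[:, 2] if self.is_3d else None
        return LocalizationTable(x=coords[:, 0], y=coords[:, 1], frame=self.frame, z=z)

    def select(self, mask_or_index) -> "LocalizationTable":
        """Row subset (boolean mask or integer index array)."""
        idx = np.asarray(mask_or_index)
        z = self.z[idx] if self.is_3d else None
        return LocalizationTable(x=self.x[idx], y=self.y[idx], frame=self.frame[idx], z=z)

    @property
    def max_frame(self) -> int:
        if self.n == 0:
            raise EmptyInputError("empty localization table has no frames")
        return int(self.frame.max())

    def to_dataframe(self) -> pd.DataFrame:
        data = {"x[nm]": self.x, "y[nm]": self.y}
        if self.is_3d:
            data["z[nm]"] = self.z
        data["frame"] = self.frame
        return pd.DataFrame(data)


@dataclass(frozen=True)
class DriftTrace:
    """Per-segment and per-frame drift relative to the reference segment.

    ``anchor_frames[i]`` is the midpoint frame of segment *i*;
    ``segment_drift[i]`` its drift vector (nm).  The reference (first)
    segment's drift is identically zero.  ``frame_drift`` holds the
    linearly interpolated drift for frames 1..max_frame.
    """

    anchor_frames: np.ndarray  # (S,) int
    segment_drift: np.ndarray  # (S, d) float, nm
    frame_drift: np.ndarray    # (F, d) float, nm; row t-1 is frame t

    def __post_init__(self):
        anchors = np.asarray(self.anchor_frames, dtype=np.int64).ravel()
        seg = np.atleast_2d(np.asarray(self.segment_drift, dtype=float))
        frm = np.atleast_2d(np.asarray(self.frame_drift, dtype=float))
        if anchors.size != seg.shape[0]:
            raise FormatError("anchor_frames and segment_drift length mismatch")
        if anchors.size == 0:
            raise EmptyInputError("drift trace needs at least one segment")
        if np.any(np.diff(anchors) <= 0):
            raise FormatError("anchor_frames must be strictly increasing")
        if not np.allclose(seg[0], 0.0, atol=1e-9):
            raise FormatError("reference-segment drift must be zero")
        if seg.shape[1] != frm.shape[1]:
            raise FormatError("segment and frame drift dimensionality mismatch")
        if anchors.max() > frm.shape[0]:
            raise FormatError("frame_drift does not cover all anchor frames")
        at_anchor = frm[anchors - 1]
        if not np.allclose(at_anchor, seg, atol=1e-6):
            raise FormatError("frame_drift must equal segment_drift at anchors")
        object.__setattr__(self, "anchor_frames", anchors)
        object.__setattr__(self, "segment_drift", seg)
        object.__setattr__(self, "frame_drift", frm)

    @property
    def ndim(self) -> int:
        return self.segment_drift.shape[1]

    @property
    def n_segments(self) -> int:
        return self.anchor_frames.size

    @property
    def max_frame(self) -> int:
        return self.frame_drift.shape[0]


@dataclass(frozen=True)
class Dialect:
    """Column mapping for reading delimited localization files.

    ``pixel_size`` (nm/pixel), when given, scales the lateral x/y columns
    from camera pixels to nm; z stays untouched.  ``sep=None`` autodetects
    the delimiter from the file extension (.tsv/.txt → tab, else comma).
    """

    x: str = "x[nm]"
    y: str = "y[nm]"
    z: Optional[str] = "z[nm]"
    frame: str = "frame"
    pixel_size: Optional[float] = None
    sep: Optional[str] = None
    z_required: bool = False


DEFAULT_DIALECT = Dialect()

_FLOAT_FMT = "%.6f"


def _resolve_sep(path: Path, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def _numeric_column(df: pd.DataFrame, name: str, path: Path) -> np.ndarray:
    raw = df[name]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna() | raw.isna()
    if bad.any():
        # +2: header row plus 1-based numbering
        lines = [str(i + 2) for i in np.flatnonzero(bad.to_numpy())[:5]]
        raise FormatError(
            f"{path}: non-numeric or missing values in column '{name}' "
            f"at line(s) {', '.join(lines)}"
        )
    return values.to_numpy(dtype=float)


def read_localizations(
    path: Union[str, os.PathLike], dialect: Dialect = DEFAULT_DIALECT
) -> LocalizationTable:
    """Read a delimited localization table and return it in nm.

    Raises
    ------
    FormatError
        If a mandatory column is missing or a value cannot be parsed
        (the message carries the offending line numbers).
    EmptyInputError
        If the file contains a header but no records.
    """
    path = Path(path)
    sep = _resolve_sep(path, dialect.sep)
    df = pd.read_csv(path, sep=sep)
    for col in (dialect.x, dialect.y, dialect.frame):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column '{col}'")
    has_z = dialect.z is not None and dialect.z in df.columns
    if dialect.z_required and not has_z:
        raise FormatError(f"{path}: missing required z column '{dialect.z}'")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no localization records")
    x = _numeric_column(df, dialect.x, path)
    y = _numeric_column(df, dialect.y, path)
    z = _numeric_column(df, dialect.z, path) if has_z else None
    frame_f = _numeric_column(df, dialect.frame, path)
    if not np.all(frame_f == np.round(frame_f)):
        raise FormatError(f"{path}: non-integer frame indices")
    if dialect.pixel_size is not None:
        x = x * dialect.pixel_size
        y = y * dialect.pixel_size
    return LocalizationTable(x=x, y=y, frame=frame_f.astype(np.int64), z=z)


def write_localizations(table: LocalizationTable, path: Union[str, os.PathLike]) -> Path:
    """Write a table as delimited text; round-trips to within 1e-6 nm."""
    path = Path(path)
    sep = _resolve_sep(path, None)
    table.to_dataframe().to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
    return path


def _axis_cols(ndim: int) -> list:
    return ["dx[nm]", "dy[nm]", "dz[nm]"][:ndim]


def _trace_paths(path: Path) -> tuple:
    stem = path.with_suffix("") if path.suffix else path
    return (
        stem.parent / f"{stem.name}_segments.csv",
        stem.parent / f"{stem.name}_frames.csv",
    )


def write_drift_trace(trace: DriftTrace, path: Union[str, os.PathLike]) -> tuple:
    """Write a drift trace as two CSVs: per-segment and per-frame.

    ``path`` is a base name; ``<base>_segments.csv`` holds
    (anchor_frame, dx, dy[, dz]) and ``<base>_frames.csv`` holds
    (frame, dx, dy[, dz]) for frames 1..max_frame.  Returns both paths.
    """
    seg_path, frm_path = _trace_paths(Path(path))
    cols = _axis_cols(trace.ndim)
    seg_df = pd.DataFrame(trace.segment_drift, columns=cols)
    seg_df.insert(0, "anchor_frame", trace.anchor_frames)
    seg_df.to_csv(seg_path, index=False, float_format=_FLOAT_FMT)
    frm_df = pd.DataFrame(trace.frame_drift, columns=cols)
    frm_df.insert(0, "frame", np.arange(1, trace.max_frame + 1))
    frm_df.to_csv(frm_path, index=False, float_format=_FLOAT_FMT)
    return seg_path, frm_path


def read_drift_trace(path: Union[str, os.PathLike]) -> DriftTrace:
    """Read back a drift trace written by :func:`write_drift_trace`."""
    seg_path, frm_path = _trace_paths(Path(path))
    seg_df = pd.read_csv(seg_path)
    frm_df = pd.read_csv(frm_path)
    ndim = sum(c in seg_df.columns for c in ("dx[nm]", "dy[nm]", "dz[nm]"))
    cols = _axis_cols(ndim)
    return DriftTrace(
        anchor_frames=seg_df["anchor_frame"].to_numpy(np.int64),
        segment_drift=seg_df[cols].to_numpy(float),
        frame_drift=frm_df[cols].to_numpy(float),
    )
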