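"""Synthetic SMLM data with known ground truth.

Two families of scenarios are generated:

* **Two-channel shift scenarios** — the same base molecular positions are
  copied to two channels, each re-scattered with independent Gaussian
  localization noise; one channel can be globally shifted and both can be
  diluted with uniform uncorrelated background.  These probe the shift
  estimator in isolation.
* **Clustered multi-frame datasets** — clusters of repeated localizations
  (≈20 per cluster, σ = 10 nm lateral scatter; in 3D, cluster depths
  uniform in ±400 nm with σ = 22 nm axial scatter) spread over a
  contiguous region occupying a fraction (default 2/3) of the camera
  field, with localizations randomly assigned to frames at a fixed
  occupancy (default 30/frame), and a smooth random drift trajectory
  injected per frame.  These emulate full STORM acquisitions.

The simulator produces localization tables directly; it does not model
camera images, PSFs, or blinking photophysics.  All randomness derives
from a single integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io import LocalizationTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_clusters",
    "simulate_two_channel",
    "simulate_drift_trajectory",
    "inject_drift",
    "simulate_smlm",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a clustered SMLM simulation.

    ``field_size`` is the camera field side in µm; coordinates are
    produced in nm.  ``cluster_density`` is in clusters/µm² over the
    feature region, which is a centered rectangle occupying
    ``region_fraction`` of the field area.
    """

    n_frames: int
    cluster_density: float            # clusters / µm²
    field_size: float = 40.0          # µm
    region_fraction: float = 2.0 / 3.0
    locs_per_cluster_mean: float = 20.0
    sigma_xy: float = 10.0            # nm, per lateral axis
    locs_per_frame: int = 30
    three_d: bool = False
    sigma_z: float = 22.0             # nm (3D only)
    z_range: Tuple[float, float] = (-400.0, 400.0)  # nm (3D only)
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1 or self.locs_per_frame < 1:
            raise ValueError("n_frames and locs_per_frame must be positive")
        if not (0 < self.region_fraction <= 1):
            raise ValueError("region_fraction must be in (0, 1]")
        if min(self.cluster_density, self.field_size, self.sigma_xy + 1) <= 0:
            raise ValueError("densities, sizes and scatters must be positive")

    @property
    def n_localizations(self) -> int:
        return self.n_frames * self.locs_per_frame

    @property
    def n_clusters(self) -> int:
        area = self.field_size**2 * self.region_fraction  # µm²
        return max(1, int(round(self.cluster_density * area)))


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator knows and an estimator must recover."""

    frame_drift: np.ndarray      # (n_frames, d) nm; zero if no drift injected
    cluster_centers: np.ndarray  # (C, d) nm
    membership: np.ndarray       # (N,) cluster id per localization


def simulate_clusters(cfg: SimulationConfig) -> Tuple[LocalizationTable, GroundTruth]:
    """Generate a drift-free clustered dataset plus its ground truth.

    Cluster centers are uniform over the feature region; the
    ``n_frames × locs_per_frame`` localizations are allocated to clusters
    multinomially with equal weights and scattered around their centers.
    Frames are assigned by random permutation so every frame holds exactly
    ``locs_per_frame`` localizations.  Fully determined by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    field_nm = cfg.field_size * 1000.0
    n_total = cfg.n_localizations
    C = cfg.n_clusters
    expected = C * cfg.locs_per_cluster_mean
    if expected > 0 and abs(n_total / expected - 1) > 0.2:
        warnings.warn(
            f"bookkeeping mismatch: {n_total} localizations over {C} clusters "
            f"gives {n_total / C:.1f} locs/cluster "
            f"(target ~{cfg.locs_per_cluster_mean:g})"
        )
    # Centered rectangle: full width, region_fraction of the height.
    y_lo = field_nm * (1 - cfg.region_fraction) / 2
    y_hi = field_nm - y_lo
    centers_xy = np.column_stack(
        [rng.uniform(0, field_nm, C), rng.uniform(y_lo, y_hi, C)]
    )
    if cfg.three_d:
        centers = np.column_stack(
            [centers_xy, rng.uniform(cfg.z_range[0], cfg.z_range[1], C)]
        )
    else:
        centers = centers_xy
    counts = rng.multinomial(n_total, np.full(C, 1.0 / C))
    membership = np.repeat(np.arange(C), counts)
    d = 3 if cfg.three_d else 2
    scatter_sd = np.array([cfg.sigma_xy, cfg.sigma_xy, cfg.sigma_z][:d])
    coords = centers[membership] + rng.normal(0.0, scatter_sd, size=(n_total, d))
    frames = np.repeat(np.arange(1, cfg.n_frames + 1), cfg.locs_per_frame)
    frames = frames[rng.permutation(n_total)]
    table = LocalizationTable(
        x=coords[:, 0],
        y=coords[:, 1],
        frame=frames,
        z=coords[:, 2] if cfg.three_d else None,
    )
    truth = GroundTruth(
        frame_drift=np.zeros((cfg.n_frames, d)),
        cluster_centers=centers,
        membership=membership,
    )
    return table, truth


def simulate_two_channel(
    density: float = 1.0,
    sigma: float = 10.0,
    shift: Sequence[float] = (0.0, 0.0),
    background_fold: float = 0.0,
    seed: int = 0,
    field_size: float = 40.0,
) -> Tuple[LocalizationTable, LocalizationTable]:
    """Two channels sharing base positions, for shift-extraction tests.

    Base molecular positions are uniform at ``density`` (per µm²) over the
    square field; each channel adds independent Gaussian scatter of
    ``sigma`` nm per axis.  The first (moving, "red") channel is globally
    shifted by ``shift`` and each channel is then augmented with
    ``background_fold`` × as many uniform uncorrelated localizations.
    Returns ``(moving, reference)`` tables (all records in frame 1).
    """
    if background_fold < 0:
        raise ValueError("background_fold must be >= 0")
    rng = np.random.default_rng(seed)
    field_nm = field_size * 1000.0
    n_base = max(1, int(round(density * field_size**2)))
    base = rng.uniform(0, field_nm, size=(n_base, 2))
    shift = np.asarray(shift, dtype=float)
    red = base + rng.normal(0.0, sigma, size=base.shape) + shift
    blue = base + rng.normal(0.0, sigma, size=base.shape)
    n_bg = int(round(background_fold * n_base))
    if n_bg:
        red = np.vstack([red, rng.uniform(0, field_nm, size=(n_bg, 2))])
        blue = np.vstack([blue, rng.uniform(0, field_nm, size=(n_bg, 2))])

    def _table(xy):
        return LocalizationTable(x=xy[:, 0], y=xy[:, 1], frame=np.ones(len(xy), np.int64))

    return _table(red), _table(blue)


def simulate_drift_trajectory(
    n_frames: int,
    amplitude: Union[float, Sequence[float]],
    smoothness: int,
    seed: int = 0,
    dim: int = 2,
) -> np.ndarray:
    """A smooth random per-frame drift trajectory, (n_frames, dim) in nm.

    A Gaussian random walk is low-pass filtered with a moving average of
    ``smoothness`` frames, pinned to zero at frame 1, and rescaled per
    axis so the peak-to-peak excursion equals ``amplitude`` (scalar or one
    value per axis; an amplitude of 0 gives a zero trajectory for that
    axis).  Deterministic given ``seed``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    amp = np.broadcast_to(np.asarray(amplitude, dtype=float), (dim,)).copy()
    if np.any(amp < 0):
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    walk = np.cumsum(rng.normal(size=(n_frames, dim)), axis=0)
    window = int(max(1, min(smoothness, n_frames)))
    smooth = uniform_filter1d(walk, size=window, axis=0, mode="nearest")
    smooth = smooth - smooth[0]
    ptp = smooth.max(axis=0) - smooth.min(axis=0)
    scale = np.divide(amp, ptp, out=np.zeros(dim), where=ptp > 0)
    return smooth * scale


def inject_drift(table: LocalizationTable, frame_drift: np.ndarray) -> LocalizationTable:
    """Shift each localization by the drift of its frame (inverse of
    drift correction: ``apply_drift(inject_drift(t, D), D) == t``)."""
    frame_drift = np.atleast_2d(np.asarray(frame_drift, dtype=float))
    if frame_drift.shape[1] != table.ndim:
        raise ValueError(
            f"drift is {frame_drift.shape[1]}D but table is {table.ndim}D"
        )
    if table.n and table.max_frame > frame_drift.shape[0]:
        raise ValueError("frame_drift does not cover all frames in the table")
    return table.with_coords(table.coords + frame_drift[table.frame - 1])


def simulate_smlm(
    cfg: SimulationConfig,
    drift_amplitude: Union[float, Sequence[float]] = 200.0,
    smoothness: Optional[int] = None,
) -> Tuple[LocalizationTable, GroundTruth]:
    """Clustered dataset with an injected smooth drift trajectory.

    ``drift_amplitude`` is the peak-to-peak excursion in nm (scalar or per
    axis).  ``smoothness`` defaults to n_frames/20, giving a trajectory
    whose features span many segments at typical segment lengths.  The
    cluster and trajectory random streams are split from ``cfg.seed``.
    """
    table, truth = simulate_clusters(cfg)
    if smoothness is None:
        smoothness = max(1, cfg.n_frames // 20)
    traj_seed = np.random.SeedSequence(cfg.seed).spawn(2)[1]
    drift = simulate_drift_trajectory(
        cfg.n_frames,
        drift_amplitude,
        smoothness,
        seed=traj_seed,
        dim=table.ndim,
    )
    drifted = inject_drift(table, drift)
    truth = GroundTruth(
        frame_drift=drift,
        cluster_centers=truth.cluster_centers,
        membership=truth.membership,
    )
    return drifted, truth
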