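"""Quality metrics for drift correction.

* ``residual_drift`` — per-frame absolute distance between an estimated
  and a ground-truth drift trajectory, after aligning both at a common
  anchor frame (box-plot style summary statistics).
* ``cloud_sigma`` — spread of a nearest-pair displacement cloud; for two
  channels with per-axis localization scatter σ_a and σ_b the expected
  pooled width is sqrt(σ_a² + σ_b²).
* ``cluster_fwhm`` — apparent cluster size after overlaying all clusters
  by their centroids; a robust (MAD-based) Gaussian-equivalent FWHM that
  inflates with uncorrected drift.
* ``z_fwhm`` — Gaussian-fit FWHM of the axial position histogram of a
  flat sample; broadens under axial drift and recovers after correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.optimize import curve_fit

from .baselines import BinnedImage, bin_localizations
from .core import DisplacementCloud
from .io import LocalizationTable

__all__ = [
    "ResidualSummary",
    "residual_drift",
    "cloud_sigma",
    "CloudSigma",
    "cluster_fwhm",
    "z_fwhm",
    "render_histogram_image",
    "FWHM_FACTOR",
]

#: FWHM of a Gaussian = 2·sqrt(2·ln 2) · σ
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

_MAD_TO_SIGMA = 1.4826  # normal-consistency factor for the MAD


@dataclass(frozen=True)
class ResidualSummary:
    """Distribution of per-frame residual drift (nm)."""

    per_frame_residual: np.ndarray
    mean: float
    median: float
    q1: float
    q3: float
    sd: float
    n_frames: int


def residual_drift(
    estimated: np.ndarray,
    truth: np.ndarray,
    anchor_frame: int = 1,
    subsample_n: Optional[int] = None,
    seed: Optional[int] = None,
) -> ResidualSummary:
    """Per-frame absolute distance between estimated and true drift.

    Both traces are first aligned by subtracting their value at
    ``anchor_frame`` (the reference segment's midpoint), making the
    comparison invariant to a common constant offset.  ``subsample_n``
    randomly samples that many frames (seeded) before summarizing.
    """
    est = np.atleast_2d(np.asarray(estimated, dtype=float))
    tru = np.atleast_2d(np.asarray(truth, dtype=float))
    if est.shape != tru.shape:
        raise ValueError(f"trace shapes differ: {est.shape} vs {tru.shape}")
    if not (1 <= anchor_frame <= est.shape[0]):
        raise ValueError("anchor_frame outside the trace range")
    diff = (est - est[anchor_frame - 1]) - (tru - tru[anchor_frame - 1])
    residual = np.linalg.norm(diff, axis=1)
    if subsample_n is not None and subsample_n < residual.size:
        rng = np.random.default_rng(seed)
        residual = residual[rng.choice(residual.size, subsample_n, replace=False)]
    q1, med, q3 = np.percentile(residual, [25, 50, 75])
    return ResidualSummary(
        per_frame_residual=residual,
        mean=float(residual.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        sd=float(residual.std(ddof=1)) if residual.size > 1 else 0.0,
        n_frames=int(residual.size),
    )


@dataclass(frozen=True)
class CloudSigma:
    """Per-axis and pooled (lateral) spread of a displacement cloud, nm."""

    per_axis: np.ndarray
    pooled: float


def cloud_sigma(cloud: DisplacementCloud, min_pairs: int = 100) -> CloudSigma:
    """Sample standard deviation of the displacements about the cloud mean.

    The pooled value is the isotropic lateral width
    sqrt((σ_x² + σ_y²) / 2).
    """
    if cloud.n_pairs < min_pairs:
        raise ValueError(
            f"{cloud.n_pairs} pairs are too few for a stable width estimate "
            f"(need >= {min_pairs})"
        )
    per_axis = cloud.displacements.std(axis=0, ddof=1)
    pooled = float(np.sqrt(np.mean(per_axis[:2] ** 2)))
    return CloudSigma(per_axis=per_axis, pooled=pooled)


def cluster_fwhm(
    corrected: LocalizationTable,
    membership: np.ndarray,
    min_cluster_size: int = 5,
) -> float:
    """Lateral FWHM of the cluster overlay (nm).

    Each qualifying cluster (≥ ``min_cluster_size`` localizations) is
    re-centered on its centroid; the pooled re-centered positions yield a
    robust per-axis σ (scaled median absolute deviation, which resists
    stray localizations) and FWHM = 2.3548 × pooled σ.
    """
    membership = np.asarray(membership)
    if membership.shape[0] != corrected.n:
        raise ValueError("membership length must match the table")
    xy = corrected.coords[:, :2]
    ids, inverse, counts = np.unique(membership, return_inverse=True, return_counts=True)
    ok = counts[inverse] >= min_cluster_size
    if not ok.any():
        raise ValueError(f"no clusters with >= {min_cluster_size} localizations")
    sums = np.zeros((ids.size, 2))
    np.add.at(sums, inverse, xy)
    centroids = sums / counts[:, None]
    # Deviations from a size-n sample centroid have sd σ·sqrt(1-1/n);
    # rescale per cluster so the pooled width estimates σ without that bias.
    debias = np.sqrt(counts / np.maximum(counts - 1, 1))
    centered = ((xy - centroids[inverse]) * debias[inverse, None])[ok]
    mad = np.median(np.abs(centered - np.median(centered, axis=0)), axis=0)
    sigma = mad * _MAD_TO_SIGMA
    pooled = float(np.sqrt(np.mean(sigma**2)))
    return FWHM_FACTOR * pooled


def z_fwhm(table: LocalizationTable, bin_width: float = 5.0) -> float:
    """FWHM (nm) of a Gaussian fitted to the axial position histogram.

    The z values are histogrammed at ``bin_width`` nm and the counts fit
    by least squares with a normal density; assumes a unimodal (flat
    sample) distribution.
    """
    if not table.is_3d:
        raise ValueError("z_fwhm requires a 3D table")
    z = table.z
    span = z.max() - z.min()
    if span <= 0:
        raise ValueError("degenerate z distribution: all values equal")
    edges = np.arange(z.min(), z.max() + bin_width, bin_width)
    if edges.size < 4:
        raise ValueError("z spread too small for a histogram fit")
    counts, edges = np.histogram(z, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, a, mu, sig):
        return a * np.exp(-((x - mu) ** 2) / (2 * sig**2))

    p0 = (counts.max(), float(np.mean(z)), float(np.std(z)))
    try:
        popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise ValueError(f"z histogram Gaussian fit did not converge: {exc}") from exc
    return FWHM_FACTOR * abs(float(popt[2]))


def render_histogram_image(
    table: LocalizationTable, grid_size: float = 15.0, bounds=None
) -> BinnedImage:
    """Render localizations as a 2D histogram image (visual QC helper)."""
    return bin_localizations(table, grid_size, bounds)
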