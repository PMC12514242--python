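# Methods

This note documents the models, conventions, numerical choices and known
limitations of `npcloud`, in the spirit of a methods appendix. Nothing here
states a result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model and conventions

A **localization table** holds one record per fitted molecule: continuous
coordinates in nm (never rounded or binned at I/O time) and a 1-based
camera-frame index. Dimensionality is uniform: either every record has a z
coordinate or none does. Record order carries no meaning. The y axis keeps
the camera convention (increasing downward); plotting-side sign flips are
left to the caller. The CSV dialect mechanism remaps arbitrary column
names and applies an optional pixel→nm scale to the lateral columns only —
z columns in SMLM exports are conventionally already calibrated in nm by
the astigmatism/biplane calibration, so the camera pixel size does not
apply to them.

A **drift trace** stores one drift vector per segment (the reference
segment's is identically zero), the segment anchor frames, and the
per-frame drift obtained by linear interpolation.

## Nearest-pair displacement clouds

`pair_nearest` matches each *moving* localization to its nearest
*reference* localization within the search radii. Matching is
one-directional and many-to-one; uniqueness constraints would bias the
cloud and are deliberately absent. Frame indices are ignored at this
level.

* **2D**: nearest by Euclidean distance, gated by the lateral radius
  r_xy (default 50 nm — comfortably above the ~14 nm pair scatter of
  σ = 10 nm channels while keeping the background contribution small).
* **3D**: candidates are gated by the cylinder {lateral distance ≤ r_xy
  and |Δz| ≤ r_z} with r_z = 100 nm by default (matching the ≈2× poorer
  axial precision of astigmatism-based 3D-STORM). Among candidates,
  "nearest" minimizes the anisotropy-normalized distance
  √((Δxy/r_xy)² + (Δz/r_z)²), which treats lateral and axial precision
  consistently. A plain-Euclidean alternative is switchable
  (`metric="euclidean"`) for sensitivity checks.
* **Ties** (equidistant candidates) are broken toward the lower reference
  record index — a measure-zero event on continuous data, fixed only for
  reproducibility. The accelerated k-d-tree search is defined by, and
  tested pair-for-pair against, the exhaustive `pair_nearest_bruteforce`
  oracle.

`cloud_mean` is the plain component-wise average of the displacements. It
refuses to answer below `n_min = 10` pairs (raising a typed error that
carries the pair count) because a smaller cloud is dominated by noise; the
literature states no floor, so a small conservative one with an explicit
error was chosen.

## Iterative shift estimation

With uncorrelated background, the radius-clipped background is symmetric
about the *origin* while the correlated cloud is centered at the shift, so
a single coordinate average underestimates the shift. The estimator
therefore iterates: shift the moving set back by the running estimate,
re-pair, re-average; each round makes the clipped background more
symmetric. Iteration stops when the new cloud-mean magnitude is no longer
smaller than the previous one; the final non-improving step is discarded
entirely (not partially applied). `max_iter = 20` bounds the runtime —
typical convergence takes well under ten rounds — and exhausting it is
reported as `converged=False` rather than silently accepted.

In 3D one joint pairing is performed per iteration, but the cloud center
is averaged separately for the lateral part and for z, and the stopping
rule tracks the xy-norm and |z| criteria independently: iteration
continues while either part still improves, and the discarded final step
is discarded as a whole.

The converged estimate is unbiased but inherits the sampling noise of the
cloud mean; its per-realization spread scales as the effective cloud width
divided by √(pair count) and grows with the background fraction. Tests
that assert accuracy under heavy (9-fold) background therefore phrase it
as accuracy of the estimate across seeds rather than of any single
realization.

## Drift-correction pipeline

* **Segmentation**: consecutive L-frame intervals starting at frame 1. A
  trailing remainder shorter than L/2 is merged into the previous segment
  (keeping per-segment statistics roughly uniform); a longer remainder
  stays as a short final segment. L is the one parameter the user must
  choose; everything else has working defaults.
* **Sequential estimation**: segment 1 is the reference with drift 0; for
  each later segment the localizations are pre-shifted by the previous
  segment's drift and the residual is estimated against segment 1, then
  added back. Correlating always against segment 1 prevents error
  accumulation; pre-shifting keeps the residual inside the small radius,
  which is also what makes the search cheap. The reference's spatial index
  is built once per pass and reused across segments.
* **Anchors and interpolation**: each segment's drift is anchored at the
  rounded midpoint of its frame interval (minimizing interpolation bias
  for smooth drift; the time stamp of a segment estimate is otherwise
  arbitrary), interpolated linearly between anchors, and extrapolated as
  a constant outside them.
* **Insufficient pairs** in a segment (sparse stretches, photobleached
  tails) inherit the previous segment's drift with a warning instead of
  aborting the run.
* **Two-pass (resampled-reference) variant**: after a first full pass, the
  corrected dataset is subsampled in frame order with a constant stride
  (start index 0, deterministic) to ≈ `resample_factor` (default 12) times
  the first segment's localization count. Pass 2 re-estimates every
  segment of the *original* data — pre-shifted by its own pass-1 drift,
  not chained sequentially, since the enlarged reference makes chaining
  unnecessary — against that reference, which lives in corrected
  coordinates. The pass-2 residual of segment 1 need not be exactly zero
  (the reference is an average over the whole corrected acquisition), so
  it is subtracted from all segments to preserve exact reference
  anchoring. Pass 2 costs about as much as pass 1.

## Correlation baselines

DCC renders each segment as a 15 nm 2D histogram (half-open bins
[edge, edge + grid)) over the common data extent and takes the peak of the
zero-padded FFT cross-correlation with segment 1. Peak search is
restricted to ±1 µm of lag (suppressing spurious far-field peaks) and
refined by the intensity centroid of the 3×3 neighborhood — the minimal
standard sub-pixel scheme; a bare integer peak would quantize the estimate
to the grid. RCC estimates all segment pairs and solves d_ij ≈ r_j − r_i
(r_1 = 0) by least squares, drops pairs whose post-fit residual norm
exceeds 30 nm (two grid cells), and re-solves once; a rank-deficient
system after removal is an error. Both are minimal comparison baselines,
2D only, and quadratic cost makes RCC impractical beyond a few hundred
segments — which is the point of the comparison.

## Simulator

The simulator emulates localization *tables*, not raw images: no PSF,
camera noise, or blinking kinetics are modeled, and per-frame localization
counts are exactly uniform rather than stochastic. Passing tests therefore
demonstrate correctness of the estimation machinery on data with ideal
Gaussian localization errors, not robustness to fitting artifacts,
repeated-blinking correlations, or density fluctuations in real samples.

* **Clustered datasets**: cluster centers uniform over a centered
  rectangle occupying `region_fraction` (default 2/3) of a
  `field_size` = 40 µm square field; total localizations
  = n_frames × locs_per_frame (default 30/frame) takes precedence over
  the nominal ~20 localizations/cluster, with per-cluster counts
  multinomial; lateral scatter σ_xy = 10 nm per axis; in 3D, cluster
  depths uniform in ±400 nm with σ_z = 22 nm scatter (FWHM ≈ 52 nm),
  matching typical astigmatism-based 3D-STORM performance. Frames are
  assigned by random permutation so occupancy is exact. A >20% mismatch
  between the frame budget and density × ~20 locs/cluster warns but does
  not error.
* **Two-channel scenarios**: shared base positions at a given density,
  independent per-channel Gaussian scatter, optional global shift of the
  moving channel, and k-fold uniform background per channel over the same
  field.
* **Drift trajectories**: a Gaussian random walk, smoothed by a moving
  average of `smoothness` frames (default n_frames/20, so the trajectory's
  features span many segments at typical L), pinned to zero at frame 1 and
  rescaled per axis to an exact peak-to-peak amplitude (default 200 nm; a
  measured stage-drift curve can be substituted wherever a per-frame array
  is accepted). Amplitudes may be set per axis, e.g. to vary axial drift
  independently of lateral.

All randomness flows from one integer seed; cluster generation and the
trajectory use independent spawned streams.

## Evaluation

Residual drift compares per-frame traces after subtracting both traces'
values at the reference segment's anchor frame (the estimate is only ever
defined relative to its reference). Cluster overlay FWHM re-centers each
cluster on its sample centroid, rescales deviations by √(n/(n−1)) to undo
the centroid-fit shrinkage, pools them, and converts a MAD-based robust σ
(chosen over the plain sd to resist stray localizations) to FWHM = 2.3548σ.
The axial FWHM fits a Gaussian to the 5 nm-binned z histogram by least
squares; degenerate (constant-z) input and non-convergent fits raise
informative errors.

## Problem sizes used in the tests

The end-to-end checks run scaled-down acquisitions — typically 2,000
frames at 30 localizations/frame (60,000 localizations, 133 segments at
L = 15) over a 20 µm field at 20 clusters/µm², and 1,000 frames for the
axial-restoration check — sizes chosen so the full suite completes in
about a minute while keeping per-segment pair counts (~40 correlated
pairs) in the regime where the method's robustness, and the binned
baseline's failure, are both clearly expressed. The simulator's presets
also generate the full-scale sparse (6,600 frames, 10 clusters/µm²,
198,000 localizations) and dense (66,000 frames, 100 clusters/µm²)
scenarios; the nearest-pair methods handle these in seconds to minutes on
one core, whereas all-pairs RCC at small L is impractical by construction.

## Known limitations

* Translation-only registration: no rotation, magnification, or
  non-rigid deformation.
* The redundant baseline is a minimal reimplementation for comparison,
  not a faithful reproduction of any published RCC code; its timings are
  indicative only.
* No 3D variants of the binned baselines.
* No raw-image reading, single-molecule fitting, cluster segmentation of
  experimental data (cluster membership must be supplied), or
  Fourier-ring-correlation analysis.
* Tie-breaking and stride choices are deterministic conventions, not
  statistically motivated.
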