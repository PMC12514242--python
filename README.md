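# npcloud

Fast, robust drift correction for single-molecule localization microscopy
(SMLM), based on nearest-pair displacement clouds.

## The problem

SMLM (STORM/PALM) builds a super-resolved image by accumulating millions of
fitted molecular positions over 10³–10⁵ camera frames. Slow mechanical and
thermal drift of the sample during that acquisition smears the accumulated
image and must be estimated and subtracted after the fact. The common
data-based approach — rendering frame segments as binned 2D histograms and
cross-correlating them — throws away the sub-grid precision of the fitted
positions and becomes unreliable exactly where it matters, at small segment
sizes and sparse data.

`npcloud` is for SMLM users and method developers who start from a
localization table (x, y\[, z\] in nm plus a frame index) and want per-frame
drift estimates without fiducial beads, grid binning, or parameter tuning.

## The method

For every localization in a *moving* set, find its nearest neighbor in a
*reference* set within a small search radius r (50 nm laterally, 100 nm
axially) and record the vectorial displacement Δ = x_moving − x_reference.
These displacements form a "cloud" whose center is the translational shift
between the two sets; uncorrelated molecules contribute a background that
is symmetric about the origin once the shift is removed. The shift is found
by iterating

&nbsp;&nbsp;s ← s + mean{Δ(moving − s, reference)}

until the cloud mean stops moving closer to the origin (the final
non-improving step is discarded). For two channels with per-axis
localization scatter σ each, the cloud width is √2·σ — pairing loses no
precision to binning.

Drift correction segments the acquisition into fixed L-frame blocks,
takes segment 1 as the reference, pre-shifts each later segment by the
previous segment's drift (so the residual fits inside r), and estimates the
residual against segment 1 — always segment 1, so errors do not accumulate.
Per-segment drifts are linearly interpolated to per-frame values and
subtracted. The two-pass variant (`rr_npcloud_drift`) re-estimates every
segment against a reference built by evenly subsampling the corrected
dataset to ~12× the first segment's size, capturing structure a single
stochastic segment misses. Grid-binned DCC and redundant RCC baselines are
included for comparison, and everything works in 3D with separate lateral
and axial search radii.

## Worked example

```python
import numpy as np
from npcloud import (SimulationConfig, simulate_smlm, rr_npcloud_drift,
                     apply_drift, residual_drift)

cfg = SimulationConfig(n_frames=2000, cluster_density=20, field_size=20, seed=0)
table, truth = simulate_smlm(cfg, drift_amplitude=150.0)   # 60,000 localizations
trace = rr_npcloud_drift(table, L=15)                      # 133 segments
corrected = apply_drift(table, trace)
res = residual_drift(trace.frame_drift, truth.frame_drift,
                     anchor_frame=int(trace.anchor_frames[0]))
print(f"mean residual {res.mean:.2f} nm, median {res.median:.2f} nm")
```

This prints

```
mean residual 1.58 nm, median 1.51 nm
```

— the per-frame distance between the estimated and the injected ~150 nm
peak-to-peak drift, i.e. the correction is good to below 2 nm on average,
far below the 10 nm localization precision being simulated.

The same workflows are available from the shell:

```bash
npcloud simulate --frames 2000 --density 20 --field-size 20 \
    --drift-amplitude 150 --seed 0 --out locs.csv --truth-out truth
npcloud correct --method rr-npcloud -L 15 --input locs.csv \
    --trace-out trace --corrected-out corrected.csv
npcloud evaluate --estimated trace_frames.csv --truth truth.csv
```

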