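# Methods

## The measurement model

A cell carries two fluorescently labelled operator arrays flanking a ~20 kb
interval downstream of an early origin. The observable per channel is the
background-subtracted integrated intensity of one focus over time. The
model for a trace is a doubling step modulated by photobleaching:

    I_c(t) = exp(-k t) · [ B_c + A_c / (1 + exp(-(t - t_mid,c)/τ)) ]

with A_c = B_c by construction (replication doubles the operator copy
number and hence the bound fluorophore count). `t_mid` is the mid-rise
point — the replication time of the array midpoint — and
Δt = t_mid(red) − t_mid(green) is the transit time of the inter-array
interval. With 10 kb arrays and 20 kb inner spacing the midpoint-to-
midpoint distance is 30 kb; rates are reported as 30/Δt kb/min. The
printed chromosome IV coordinates (lacO at 332,960, G4 at 344,119, tetO at
352,560) give 19.6 kb spacing and an 8.4 kb obstacle-to-tetO distance; the
package defaults to the nominal 30 kb convention and exposes the
coordinate-derived layout (including a 30.6 kb mid-array variant via
`array_len_kb=11`) through `chr4_layout`.

Assumptions: a single fork from the origin side replicates both arrays in
order (cells replicated from the distal side appear as Δt ≤ 0 and are
flagged `reverse_orientation`, excluded by default); bleaching is a single
multiplicative exponential per channel (constant illumination); the rise
has finite duration τ = rise_time/4, with rise_time ≈ array length / fork
speed (~6.7 min by default), since duplicating the array takes as long as
replicating it.

## Synthetic-data generator

The generator defines the study conditions; it emulates, with ground
truth:

* **Fork-speed variability** — per-cell speed v ~ log-normal with mean 1.5
  kb/min (a typical budding-yeast fork) and CV 0.2. Log-normal was chosen
  for positivity and right skew, the standard choice for rates.
* **Origin firing** — Normal(20, 5) min, truncated at zero. Firing spread
  is needed so midpoints land at different places in the acquisition
  window, as in synchronized-release experiments; the values are a design
  choice, not a measured quantity.
* **Two-state obstacle** — a G4 insert is folded in a given cell with
  probability `folded_fraction`; only folded cells pause, with
  Exponential(`pause_mean`) pauses (memoryless single barrier). A
  `fixed` pause model exists for deterministic tests. Unfolded cells
  replicate at wild-type speed — this is the bimodal mixture that produces
  WT-like cells within obstacle-carrying strains.
* **Acquisition** — 1-min frames, 2 channels, 12 z-sections 0.7 µm apart;
  128×128 pixels at 0.15 µm (a 63×/1.4 objective with a 1.6× optovar on a
  16 µm-pixel EM-CCD), PSF σ_xy 0.15 µm / σ_z 0.35 µm, background 100
  photons/voxel, read noise 5, bleach rate 0.002/min, spot amplitude 2000
  integrated photons before replication. At this sampling the PSF is ~1
  pixel σ laterally and ~0.5 voxel axially — the axial undersampling is a
  property of the real acquisition geometry, not a simplification.
* **Movies** — spots are rendered by per-axis Gaussian CDF differences
  (erf), not point samples, so the integrated amplitude is exact even at
  σ_z = 0.5 voxel; per-cell random-walk drift (0.01 µm/frame) moves both
  channels together; noise is Poisson shot noise plus Gaussian read noise,
  clipped at zero.
* **Closed-form check** — for log-normal v, E[1/v] = (1+CV²)/mean, so
  E[Δt] = d·(1+CV²)/v̄ + folded_fraction·pause_mean. This is used both to
  verify the sampler and to configure scenario pairs with an exact
  expected Δt ratio.

What the simulator does *not* emulate: cell bodies and segmentation,
division and lineage, focus splitting into resolvable sisters, non-uniform
background, z-drift of the stage, photophysics beyond mono-exponential
bleaching. Passing tests therefore demonstrate correctness of the
analysis given the assumed point-spot + background model, not robustness
to segmentation or background-structure artefacts of real movies.

## Spot detection, photometry, tracking

Detection is a difference-of-Gaussians band-pass (small σ = PSF in voxel
units per axis, large σ = 1.6×), 3D local maxima (3×3×3), thresholded at
k·σ̂ with k = 5 and σ̂ the MAD-based robust scale of the filtered volume.
Maxima within 2 detection σ of the lateral border are discarded: edge
padding inflates the filtered field's variance there relative to the
interior-calibrated threshold (empirically most pure-noise false positives
sat on the border), and such spots cannot be measured with a complete
background shell anyway. Sub-voxel positions are intensity-weighted
centroids on the raw volume. Detections closer than `merge_radius_vox`
are merged with summed response, because transiently resolved sister foci
carry the same total operator-bound fluorescence the assay reads.

Intensities are measured on the raw volume (band-passing distorts
integrated photometry): sum over an anisotropy-scaled core ellipsoid
(r = 0.45 µm) minus the median of a surrounding shell (0.65–1.1 µm) times
the core voxel count. Measurements with a clipped shell are flagged; a
value may be negative on noise and is left to QC.

Tracking is greedy nearest-neighbour linking in physical units (so the
0.7 µm z-step is weighted correctly), candidates sorted by distance with
ties broken by intensity, displacement cap 0.8 µm/frame, gap closing up to
2 frames. On well-separated spots this coincides with exhaustive
minimal-cost matching (tested by enumeration). Green/red tracks are
paired by mutual nearest median position within 2 µm; unpaired tracks are
reported and excluded; missing frames stay NaN and are never interpolated.

## Sigmoid fitting and QC

Nonlinear least squares (trust-region reflective) on the bleach-aware
logistic, requiring ≥ 20 finite points. Initialization: B = median of the
first quartile of frames, A = median of the last quartile − B, t_mid =
argmax of the Gaussian-smoothed first difference, τ = 3 frame intervals,
bleach 0. Bounds: B > 0, A ≥ 0, t_mid within 10 min of the observation
window, 0 ≤ bleach ≤ 1/min, τ positive and at most the window length.
Optimizer failure yields `converged=False`, never an exception. The
mid-rise point is the fitted `t_mid` parameter, not a threshold crossing
of raw data; bleaching is handled inside the fit rather than by
pre-detrending, which would bias the step. On a constant trace the fit
correctly returns A ≈ 0; on a *noisy* flat trace the parameters are
unconstrained (any sufficiently slow sigmoid is equivalent) and rejection
is QC's job.

QC (defaults): both channels converged, r² ≥ 0.8, fold-increase (B+A)/B in
[1.4, 2.6] (the doubling design predicts 2), t_mid ≥ 5 min inside the
window on both channels, Δt > 0. Every failure carries machine-readable
reasons. The exclusion rules are this package's own definitions.

## Cohort statistics

Mean, SEM (sample SD over √n), histograms with fixed-width bins anchored
at 0. The two-sample comparison is a Monte Carlo resampling test
implemented as a label-permutation test on the difference of means,
two-sided by default, p = (#exceedances + 1)/(N + 1) with N = 1,000,000 by
default (test suites use 10⁴ with fixed seeds). The add-one correction
keeps p in (0, 1]. For the two-sided statistic the pooled values are
sorted and the smaller group size is resampled — the |mean difference|
permutation distribution depends only on the pooled multiset and the
unordered group sizes — which makes A↔B label swaps bit-identical under
the same seed. A bootstrap variant (both groups drawn with replacement
from the pool) is available for sensitivity analysis. Exact ties are
counted as exceedances with a relative tolerance of 1e-9 so integer-valued
data reproduce exhaustive enumeration. Fold-changes are ratios of mean
Δt, equal to fold-decreases in rate over a fixed distance. No
multiple-testing correction by default (per-comparison stars at
0.05/0.005/0.0005/0.00005); Benjamini–Hochberg is available behind a flag.
Whether the original statistic was the mean difference is not documented
anywhere we could check; the mean was chosen as the simplest statistic
consistent with reporting means ± SEM.

## Melting curves and gels

Raw A295 melting curves are normalized with linear baselines fitted to the
lowest- and highest-temperature quartiles; values outside [−0.1, 1.1]
trigger a warning but are reported unclipped (clipping would bias the
fit). The two-state fit is the unimolecular van 't Hoff form in absolute
temperature,

    θ(T) = 1 / (1 + exp(−(ΔH/R)(1/T − 1/Tm))),

with ΔS = ΔH/Tm pinned at the midpoint; initialization Tm at the
interpolated 0.5 crossing and |ΔH| = 40 kcal/mol with sign from the data
trend. Curves that never cross 0.5 return `converged=False` with a
diagnostic; fitted ΔH < 0 (signal rising with temperature) is flagged
`non_standard`. Residual linear baselines can be co-fitted.

Gel lanes are 1D profiles (image-to-profile extraction is out of scope):
rolling-minimum baseline (window = lane length/10, then a matched uniform
smooth), trapezoidal band areas over named windows. The full-length
fraction is reported relative to all *extension products* by default — the
unextended primer band is excluded from the denominator, since completed
synthesis among initiated events is the quantity of interest — with an
include-primer variant reported alongside.

## Problem sizes and numerical choices

The acceptance-style checks run at: 1000 null cohort pairs × 10⁴
resampling iterations (calibration); 25-cell cohorts in 128×128×12×180
movies for the end-to-end ratio recovery at configured Δt ratios 1.0, 1.5
and 2.0 (one movie per cohort, ~30 s each to simulate and analyze); 50
seeds for melting-fit recovery. These sizes were chosen so the whole
suite completes in a couple of minutes while keeping Monte Carlo error
well below the tested tolerances. All randomness flows through
`numpy.random.Generator` objects seeded explicitly; the same seed gives
bit-identical outputs.

## Known limitations

* The detector's 5σ threshold is calibrated per volume from the MAD of the
  filtered field; volumes dominated by foreground (many spots in a small
  field) would inflate the noise estimate slightly.
* Greedy linking is optimal only for well-separated spots; crossing
  trajectories closer than the displacement cap can swap identities. The
  assay's foci are sparse (two per cell, cells immobilized), so this is
  not limiting here.
* The bleach-aware sigmoid assumes the plateau is reached inside the
  observation window; midpoints near the window edge are excluded by QC
  rather than extrapolated.
* Negative-Δt cells (distal-side forks) are excluded by default, which
  censors the (rare) opposite-orientation events rather than modelling
  them.
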