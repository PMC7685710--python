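# Methods

This note records the model assumptions, parameter choices, numerical
decisions, and known limitations of `endosim`. All defaults live in
`endosim.config.ExperimentConfig` and in the per-module constants they
mirror.

## Ground-truth scene

Neurons are hard spheres with a non-fluorescent nuclear core. Radii are drawn
from N(7.95, 1.31²) µm truncated above 1 µm; shell widths from N(4, 1²) µm
truncated to (0, radius]. Placement is uniform rejection sampling with a
budget of 50 attempts per target cell; the target count is density × volume
(83,100 cells/mm³ × 0.02 mm³ = 1662 cells in the default volume). Exhausting
the budget returns a partial volume with a warning.

### Spiking and the common-input model

Each neuron fires as the sum of a private Poisson process and a shared
common-input component. The binary synchronicity matrix is Erdős–Rényi with
link probability p = 0.8 on unordered pairs. Per-pair independent common
processes cannot produce a population-mean correlation of ~0.08 at ~1.6k
neurons — with rates constrained to sum to a fixed per-neuron budget, the sum
of a neuron's pairwise correlations is bounded by the common-rate fraction,
so the mean correlation is bounded by ~1/N. We therefore model the common
input as one global Poisson source; every neuron with at least one link
receives an independent thinning of it (keep probability p), carrying a
fraction q of its mean rate, with the private process making the total rate
exact. The spike-count correlation between two linked neurons is then q·p
analytically, and q = 0.105 is calibrated once so that p·q = 0.084. The AR(1)
filter applies the same kernel to both traces of a pair, so the calcium
correlation equals the spike-count correlation; the calibration is
rate-independent.

Because all correlated pairs share a single source, their sampling errors
co-fluctuate: the population-mean correlation of one volume has a standard
deviation of ~0.017 at 1500 frames and ~0.007 at 6000 frames (measured over
seeds). Averages over several volumes are used wherever this quantity is
asserted.

### Rate units

The mean rate ρ = 0.4 is interpreted as spikes per second and converted to a
per-frame Poisson rate at the 5 Hz frame clock (0.08/frame). At 0.4
spikes/frame the calcium trace never returns to rest under γ = 0.7, the trace
baseline becomes activity-dominated, and every ROI's peak-SNR saturates near
15 — which would make segmentation thresholds of 20–30 vacuous. At 0.4
spikes/s traces show sparse transients and the peak-SNR distribution spans
the full threshold sweep. `simulate_spikes` itself is unit-agnostic (rate per
frame); the conversion happens in `simulate_activity`.

### Fluorescence

F = baseline + amplitude · cⁿ/(cⁿ + kdⁿ) with baseline 0, amplitude 1500,
n = 1, kd = 1, plus N(0, 0.05) noise per neuron and frame. The Hill form is
the standard saturating indicator model consistent with the listed parameter
names; no additional supralinearity terms are included.

## Optics

Each probe bundles focal shells, PSF curves, a magnification model, and an
intensity mask:

* **Corrected**: one spherical shell, curvature radius 400 µm; lateral/axial
  FWHM constant at 1/8 µm. Quadratic magnification 0.76 − 6.24e-4·r +
  1.95e-5·r²; mask = Gaussian fall-off with σ = 400 µm.
* **Uncorrected**: two shells, radii 265 and 2000 µm (both apex at z = 0, the
  top of the volume, curving into the tissue); lateral FWHM 1→2 µm and axial
  8→40 µm from center to 250 µm via symmetric quartics with equal weight on
  the r² and r⁴ terms; magnification 0.73 − 2.91e-4·r + 8.11e-6·r²; mask σ =
  200 µm.

The PSF quartic coefficients and the Gaussian mask fall-offs are package
defaults chosen to satisfy the qualitative constraints of the optical
characterization (homogeneous corrected resolution; uncorrected axial
resolution crossing 10 µm well inside the FOV, which puts the uncorrected
effective-FOV radius at ~84 µm; stronger edge dimming without correction).
They are not measured curves and can be overridden per probe, including from
tabulated CSV resolution data via `characterize_psf_stack` fits.

**Magnification and pixel calibration.** The printed quadratics are absolute
magnifications relative to the objective alone; the simulator uses the
relative distortion D(r) = M(r)/M(0), integrating dr/dρ = 1/D to map nominal
(uniform 2.5 µm/px) pixel radii to calibrated true radii. The nominal pixel
pitch therefore holds exactly at the FOV center, and all reported distances
(ROI centroids, pair distances, radial distances) are calibrated µm. The
dark-noise edge regime is defined on the nominal pixel grid (beyond the
250 µm ring of the 500 µm FOV).

**PSF characterization.** Bead-stack profiles through the peak voxel are fit
with Gaussians; the axial profile may instead be fit with a sum of two
Gaussians (initialized from detected local maxima), preferred when it cuts
the residual sum of squares by >20% and the peak separation exceeds the
lobes' own FWHM — the axial resolution is then the peak separation. Replicate
groups are screened for outliers at 3.5 MAD (median absolute deviation), a
standard robust screen standing in for proprietary outlier-removal software.
Resolution-vs-radius data are fit with symmetric quartics (even powers only,
respecting the cylindrical symmetry), and the effective-FOV radius is the
first up-crossing of the fitted axial curve through 10 µm (bisection to
0.1 µm).

## Scanner

The excitation volume at each pixel is an ellipsoid of revolution with
half-axes equal to the local lateral/axial FWHM (configurable scale factor,
default 1.0), its axial axis orthogonal to the focal shell; for the
uncorrected probe a pixel carries one ellipsoid per shell and voxels are
counted over their union. Voxel membership is voxel-center-in-ellipsoid on
the world grid; voxels outside the tissue slab are clipped. Per-pixel totals
are computed exactly for one representative pixel per 1-px radial ring and
reused across the ring (the ellipsoid shape and tilt depend only on radius;
azimuthal lattice variation is <1%); neuron-shell intersection counts are
exact per pixel. Nucleus voxels carry no fluorescence and count as background
voxels.

Pixel values follow three regimes:

1. **Edge** (nominal radius >250 µm): mean from the printed two-component
   Gaussian mixture (weights 0.37/0.63, means 137.48/126.83, sds 48.96/5.02),
   per-frame sd = 1.57·mean − 175.39, clamped at a floor of 1 count.
2. **Background** (no neuron voxel in the excitation volume): mean from
   lognormal(5.43, 0.36) scaled by the intensity mask, sd = 18.28·√mean −
   162.55, clamped.
3. **ROI pixels**: the mean value averages neuron fluorescence and
   background-voxel means over all voxels in the excitation volume(s), scaled
   by the mask; noise is drawn once per pixel and frame with sd =
   16.94·√(pixel mean) − 132.44, clamped. The sd fit was calibrated on pixel
   traces, so it is applied at the pixel level: drawing independent noise per
   voxel and averaging would shrink the rendered pixel noise by √(number of
   voxels) — thousands — under-dispersing pixels relative to the data the fit
   came from and, perversely, rewarding a large aberrated excitation volume
   with artificially clean pixels.

The mask scales light-derived means *before* noise generation (it is an
excitation-efficiency profile); detector dark noise is not masked. Scan order
within a frame is irrelevant (frames are snapshots; no intra-frame temporal
skew). Frames are clamped at zero. Every pixel records which neurons
contributed voxels (provenance), the ground-truth link used by segmentation.

## Segmentation and traces

Initial footprints are the provenance pixel sets per neuron. Footprints with
fewer than 5 pixels are dropped (options 5/10/15); pairs whose shared pixel
count exceeds 80% of the smaller footprint (options 70/80/90%) are linked and
linked groups merged transitively — union of pixels and of source ids — which
makes the result independent of examination order. Peak-SNR = (peak −
baseline mean)/baseline sd, with the baseline being samples below the trace's
25th percentile and the peak searched within ±1 frame of the global maximum;
it is computed on the extracted trace after merging. Trace extraction ranks a
ROI's pixels by individual peak-SNR and greedily accumulates them while the
mean trace's peak-SNR improves.

Deconvolution is nonnegative least squares against the impulse-response
convolution matrix of an AR model (order 1 below 2 Hz, else order 2), with
coefficients estimated by Yule-Walker on the noise-corrected autocovariance
(noise level from the high-frequency power spectrum) and the AR polynomial
projected back inside the unit circle if needed. The baseline subtracted
before inversion is the mean of the sub-25th-percentile samples. Events below
1e-8 of the maximum are treated as numerical dust.

## Pairwise-correlation analysis

Correlations are computed on deconvolved calcium. Nearby pairs have centroid
distance <20 µm; their correlation is normalized by subtracting the mean
correlation of distant pairs (>60 µm) in the same radial-distance bin (5
equal-width bins over [0, 250] µm; an empty bin falls back to the global
distant mean and is flagged). A pair's radial distance is the distance of the
midpoint of the segment joining the two centroids from the FOV center. The
regression slope of normalized correlation on radial distance is tested with
a two-sided permutation test (5000 label permutations, unsmoothed p, exact
enumeration when n! ≤ 1e5).

## Behavior

Whisking: centered moving standard deviation over 400 ms, Gaussian-smoothed
(σ = 25 ms, half the stated 50 ms window); the amplitude threshold maximizes
Youden's J against a labeled subset (~1/10 of the trace); events shorter than
200 ms are discarded and gaps under 0.5 s bridged. Locomotion (40 Hz wheel
speed): instantaneous >1 cm/s AND zero-phase 2nd-order 0.25 Hz low-pass
>1 cm/s AND 2-s mean >0.1 cm/s, gaps under 0.5 s merged. Pupil: Otsu
threshold, largest dark region, ellipse major axis; missing frames linearly
interpolated. A frame inherits a behavior when it covers >50% of the frame's
exposure window; states are Q/W/L/WL with A = W ∪ WL.

## Information theory

Responses (deconvolved calcium per frame) are discretized into equipopulated
bins (2 by default; ties at a bin edge go to the lower bin, with a fallback
so non-constant data never collapse into one bin). Quadratic extrapolation:
plug-in MI on the full sample, 2 random halves, and 4 random quarters
(averaged per fraction), quadratic in 1/N extrapolated to the intercept,
clamped at zero. Balanced estimates sample n_T points per state (n_T = rarer
state's occupancy) per iteration, 100 iterations; significance compares the
mean against the 95th percentile of 500 label-shuffled estimates computed
with the same settings (one balanced estimate per shuffle). Estimates with
n_T < 10 are flagged unstable. Pair co-information I(S;R1,R2) − I(S;R1) −
I(S;R2) uses the joint 4-symbol response; every term is bias-corrected and
permutation-subtracted with the same permutations, and significance uses the
central 95% of the permutation null. SVM decoding uses an RBF SVC with a
fixed hyperparameter grid (C ∈ {0.1, 1, 10, 100}, γ ∈ {scale, 0.1, 1}),
10-fold stratified CV on a balanced train half, and converts the test-half
confusion matrix to mutual information. Population curves pool ROIs within
1/4, 2/4, 3/4, and the full FOV radius; empty steps carry the previous value
and are flagged. All information is in bits.

## NMF ensembles

The module count k is selected by factorizing the train half for k = 1..n,
projecting the test half onto the fixed ROI basis (per-frame NNLS), training
an LDA on the train activations, and stopping at the first k whose successor
improves balanced accuracy by less than 0.4 percentage points. The final
factorization is multi-restart scikit-learn NMF (best reconstruction error).
Sparseness is Σw²/(Σw)² (participation-ratio form: 1 for a single dominant
ROI, 1/n for uniform weights — the printed formula is typographically garbled
and was reconstructed from its stated interpretation). WMI = (mean act_A −
mean act_Q)/(mean act_A + mean act_Q). Spatial spread is the exact shortest
open path through the 10 highest-weight ROIs (Held-Karp subset DP; brute
force cross-checked ≤8 nodes). Module membership for the Jaccard index is
weight >1e-6 of the module maximum. Shuffle nulls permute weights over ROI
identities (similarity null) or ROI positions over the FOV (spatial null);
single-ROI modules are excluded.

## What the simulator does and does not emulate

It reproduces: curved focal geometry, radially varying and double-lobed
excitation, magnification distortion, edge dimming, calibrated pixel-noise
statistics, source mixing and its consequences for segmentation, SNR, and
pairwise correlations. It does not model: photon shot-noise physics or
detector gain, motion artifacts, bleaching, neuropil/dendritic morphology,
indicator kinetics beyond AR(1)+Hill, or the tissue scattering that shapes
real intensity masks. Passing tests therefore validate the analysis stack and
the geometry-driven claims, not absolute photon budgets.

## Problem sizes

Defaults used by the test suite and the acceptance script: ground-truth
correlation from 5–6 volumes (full 1662-neuron scenes) at 1500–6000 frames;
imaging comparisons from 5 matched FOV pairs at 300 frames, full 500 µm FOV
at 2.5 µm/px, with the full printed neuron density. These sizes give
regression slopes and paired comparisons with comfortable margins while a
full run stays around ten minutes on one CPU.

## Known limitations

* The per-ring reuse of the total voxel count ignores sub-voxel azimuthal
  lattice variation (<1% of the count).
* Yule-Walker AR estimates are biased on short or noiseless traces; the
  deconvolution contract is exact only given the generating coefficients.
* The uncorrected probe's PSF/mask defaults are parametric stand-ins, not
  measured curves; absolute slope magnitudes (not their signs or
  significance) depend on them.
* The LDA elbow rule returns n_ROIs when performance never flattens, flagged
  by inspection of the returned curve rather than an exception.
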