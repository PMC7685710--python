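# endosim

In-silico two-photon calcium imaging through GRIN-lens microendoscopes, with
the analysis stack needed to quantify what optical aberration correction buys
you: signal-to-noise, segmentation yield, and — critically — unbiased
estimates of correlated neuronal activity across the field of view.

## Who this is for

Implantable gradient-index (GRIN) microendoscopes give optical access to deep
brain regions, but their intrinsic off-axis aberrations curve the focal plane
and stretch the excitation point-spread function (PSF) toward the edge of the
field of view (FOV). For population calcium imaging this is not just a
cosmetic blur: an axially elongated PSF samples several cells at once, so
pairs of nearby ROIs at the FOV margin appear *more correlated than they are*.
`endosim` forward-simulates this physics from a fully known ground truth, so
the artifact — and its removal by corrective micro-optics — can be measured
exactly.

## The model

**Scene.** Neurons are non-overlapping spheres (radius ~ N(7.95, 1.31²) µm)
with a non-fluorescent nucleus (shell width ~ N(4, 1²) µm), placed uniformly
in a 500×500×80 µm³ volume at 83,100 cells/mm³. Spiking is Poisson
(0.4 spikes/s) with a shared common-input source: each linked neuron receives
an independently thinned copy (keep probability p = 0.8) of one common train
carrying a fraction q = 0.105 of its rate, giving a mean pairwise spike/
calcium correlation of p·q = 0.084. Calcium follows an AR(1) model
(c_t = 0.7 c_{t−1} + s_t at 5 Hz) and fluorescence a Hill saturation
F = 1500 · c/(c + 1) with additive Gaussian noise (var 0.05).

**Optics.** Each probe type is a bundle of spherical focal shells, symmetric
quartic FWHM-vs-radius curves, a quadratic magnification fit, and a radial
intensity mask. The corrected probe has one shell (R = 400 µm) and a
homogeneous PSF (1 µm lateral / 8 µm axial FWHM); the uncorrected probe has
two shells (R = 265 and 2000 µm) and a PSF broadening to 2/40 µm at the FOV
edge.

**Scanner.** The excitation ellipsoid is scanned along the shell(s), always
orthogonal to the local surface; every volume voxel (0.5×0.5×1 µm³) inside it
contributes. Pixels follow a three-regime calibrated noise model (dark-edge
Gaussian mixture, lognormal background, and sqrt-mean noise for ROI pixels).

**Analysis.** Ground-truth segmentation (footprint pruning at ≥5 px, merge at
>80% overlap, peak-SNR filter), greedy trace extraction, nonnegative AR
deconvolution, power-ratio SNR, and the radial pairwise-correlation test:
correlations of nearby ROI pairs (<20 µm) normalized by distant pairs
(>60 µm) at matched radial distance, regressed on radial distance with a
5000-permutation slope test. Behavioral-state classification (Q/W/L/WL),
bias-corrected mutual information (direct method, quadratic extrapolation,
balanced resampling), pairwise synergy/redundancy, SVM population decoding,
and NMF ensemble analysis mirror the workflow used on real recordings.

## Worked example

```python
import numpy as np
from endosim.config import ExperimentConfig
from endosim.runner import simulate_fov, analyze_fov

cfg = ExperimentConfig(n_frames=300)
for probe in ("uncorrected", "corrected"):
    vol, act, ts = simulate_fov(cfg, probe, seed=42)
    res = analyze_fov(cfg, vol, act, ts)
    print(probe, res["n_rois"], round(float(np.nanmean(res["snr"])), 2),
          round(float(np.nanmean(res["source_corr"])), 3))
```

prints (one 500 µm FOV, 1662 neurons, peak-SNR threshold 20):

```
uncorrected 119 8.14 0.589
corrected 239 10.65 0.757
```

The corrected probe segments about twice as many ROIs above threshold, with
higher power-ratio SNR (the ratio of deconvolved-calcium power to residual
power) and a higher correlation between each ROI and its ground-truth source
neuron. Pooling five such matched FOV pairs and regressing the normalized
nearby-pair correlation on radial distance gives a significantly positive
slope (~2.6e-3 per µm, permutation p < 1e-4) for the uncorrected probe and a
slope indistinguishable from zero (p ≈ 0.45) for the corrected one — the
correlation-vs-radius artifact appears with aberrated optics and disappears
with correction.

A command-line interface mirrors the library:

```bash
endosim fig4 --seed 1 --out runs/fig4        # matched-probe comparison
endosim simulate --seed 1 --probe corrected --out runs/sim
```

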