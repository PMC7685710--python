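"""Comparison statistics for segmented calcium signals: power-ratio SNR,
ground-truth correspondence, the radial pairwise-correlation analysis, the
permutation regression test, and ROI density.

The central question these metrics answer: does off-axis optical aberration
artificially inflate correlations between nearby cells at the edge of a
curved field of view? Nearby-pair correlations are normalized by distant-pair
correlations at matched radial distance, and their dependence on radial
distance is tested with a permutation test on the regression slope.
"""

from __future__ import annotations

from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd

__all__ = [
    "snr_power_ratio",
    "ground_truth_match",
    "normalized_pairwise_correlation",
    "slope_permutation_test",
    "roi_density",
]


def snr_power_ratio(F_raw: np.ndarray, Cdf: np.ndarray) -> float:
    """power(Cdf) / power(F_raw - Cdf) on z-scored inputs."""
    f = np.asarray(F_raw, dtype=float)
    c = np.asarray(Cdf, dtype=float)
    if f.shape != c.shape:
        raise ValueError("traces must have equal length")
    resid = f - c
    denom = float(np.sum(resid**2))
    if denom == 0:
        raise ValueError("SNR undefined: zero residual power")
    return float(np.sum(c**2) / denom)


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def ground_truth_match(
    roi_trace: np.ndarray, candidates: np.ndarray
) -> list[tuple[int, float]]:
    """Pearson correlation of a ROI trace with each ground-truth candidate,
    sorted descending.

    The first entry identifies the source neuron; the second, when present,
    measures contamination by other merged neurons. Zero-variance candidates
    are skipped.
    """
    cands = np.atleast_2d(np.asarray(candidates, dtype=float))
    if cands.shape[0] < 1:
        raise ValueError("at least one candidate required")
    x = np.asarray(roi_trace, dtype=float)
    out = []
    for i in range(cands.shape[0]):
        y = cands[i]
        if x.std() == 0 or y.std() == 0:
            continue
        out.append((i, float(np.corrcoef(x, y)[0, 1])))
    out.sort(key=lambda t: -t[1])
    return out


def _pair_table(positions: np.ndarray, traces: np.ndarray) -> pd.DataFrame:
    n = positions.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    d = np.linalg.norm(positions[iu] - positions[ju], axis=1)
    mid = 0.5 * (positions[iu] + positions[ju])
    dist_r = np.linalg.norm(mid, axis=1)
    cm = np.corrcoef(traces)
    return pd.DataFrame(
        dict(i=iu, j=ju, pair_distance_um=d, dist_r_um=dist_r,
             correlation=cm[iu, ju])
    )


def normalized_pairwise_correlation(
    positions: np.ndarray,
    traces: np.ndarray,
    nearby_max_um: float = 20.0,
    distant_min_um: float = 60.0,
    radial_bins: int = 5,
    radial_range_um: tuple[float, float] = (0.0, 250.0),
) -> pd.DataFrame:
    """Distance-normalized correlations of nearby ROI pairs.

    ``positions`` are calibrated FOV-centered (x, y) in µm, ``traces`` the
    frame-aligned activity (one row per ROI). Nearby pairs (center distance
    below ``nearby_max_um``) get the mean correlation of distant pairs
    (above ``distant_min_um``) in the same radial-distance bin subtracted;
    a bin with no distant pairs falls back to the global distant mean and is
    flagged. The pair's radial distance is that of the midpoint of the
    segment connecting the two centers.
    """
    positions = np.asarray(positions, dtype=float)
    traces = np.asarray(traces, dtype=float)
    if positions.shape[0] < 2:
        raise ValueError("need at least two ROIs")
    sd = traces.std(axis=1)
    ok = sd > 0
    pairs = _pair_table(positions[ok], traces[ok])
    edges = np.linspace(*radial_range_um, radial_bins + 1)
    pairs["radial_bin"] = np.clip(
        np.digitize(pairs["dist_r_um"], edges) - 1, 0, radial_bins - 1
    )
    distant = pairs[pairs["pair_distance_um"] > distant_min_um]
    global_mean = float(distant["correlation"].mean()) if len(distant) else 0.0
    bin_means = distant.groupby("radial_bin")["correlation"].mean()

    nearby = pairs[pairs["pair_distance_um"] < nearby_max_um].copy()
    ref = nearby["radial_bin"].map(bin_means)
    nearby["fallback"] = ref.isna()
    nearby["normalized_correlation"] = nearby["correlation"] - ref.fillna(global_mean)
    return nearby.reset_index(drop=True)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    den = float(np.dot(xc, xc))
    if den == 0:
        raise ValueError("constant x: slope undefined")
    return float(np.dot(xc, y - y.mean()) / den)


def slope_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 5000,
    rng: np.random.Generator | None = None,
    exact_limit: int = 100_000,
) -> tuple[float, float]:
    """OLS slope of y on x with a two-sided permutation p-value.

    The null distribution is built by permuting y relative to x; p is the
    fraction of permuted |slopes| at least as large as the observed one
    (unsmoothed, so a slope larger than every permutation reports p = 0).
    All n! permutations are enumerated when feasible.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    rng = np.random.default_rng() if rng is None else rng
    slope = _ols_slope(x, y)

    n = x.size
    xc = x - x.mean()
    den = float(np.dot(xc, xc))
    yc = y - y.mean()
    if n <= 12 and factorial(n) <= exact_limit:
        perms = np.array(list(permutations(range(n))))
        null = (yc[perms] @ xc) / den
    else:
        idx = np.argsort(rng.random((n_perm, n)), axis=1)
        null = (yc[idx] @ xc) / den
    p = float(np.mean(np.abs(null) >= abs(slope) - 1e-15))
    return slope, p


def roi_density(
    mean_image: np.ndarray,
    rois,
    edge_mask: np.ndarray,
    pixel_area_um2: float = 1.0,
    percentile: float = 85.0,
) -> float:
    """ROIs per unit bright area.

    The brightness threshold is the given percentile of the edge (dark-noise)
    pixel intensities; FOV parts below it are discarded and the ROI count is
    divided by the remaining bright area.
    """
    mean_image = np.asarray(mean_image, dtype=float)
    edge_mask = np.asarray(edge_mask, dtype=bool)
    thr = np.percentile(mean_image[edge_mask], percentile)
    bright = (mean_image > thr) & ~edge_mask
    area = float(bright.sum()) * pixel_area_um2
    if area == 0:
        raise ValueError("zero bright area")
    return len(rois) / area
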