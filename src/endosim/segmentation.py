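"""Ground-truth-based segmentation of simulated t-series and trace
extraction/deconvolution.

Each neuron's initial footprint is the set of pixels that collect signal
from it (the simulator's provenance). Footprints smaller than ``min_px``
are discarded; footprints overlapping by more than ``overlap_frac`` of the
smaller one are merged transitively. Traces are extracted by a greedy
pixel-subset selection that maximizes peak-SNR, and deconvolved under a
sparse non-negative autoregressive model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.signal import welch

__all__ = [
    "ROI",
    "ROISet",
    "TraceSet",
    "segment_ground_truth",
    "peak_snr",
    "filter_by_peak_snr",
    "extract_trace",
    "deconvolve",
    "segment_and_extract",
]


@dataclass
class ROI:
    """A segmented region: pixel set, provenance, trace, and quality stats."""

    pixels: np.ndarray  # flat pixel indices, sorted
    source_neuron_ids: tuple[int, ...]
    centroid_um: tuple[float, float] | None = None  # calibrated, FOV-centered
    dist_r_um: float | None = None
    trace: np.ndarray | None = None
    peak_snr: float | None = None

    @property
    def n_px(self) -> int:
        return len(self.pixels)


@dataclass
class ROISet:
    rois: list[ROI] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def __getitem__(self, i):
        return self.rois[i]


@dataclass
class TraceSet:
    """Raw traces with their deconvolution products, frame-aligned."""

    raw: np.ndarray  # (n_rois, n_frames)
    calcium: np.ndarray  # denoised/deconvolved calcium, >= 0
    events: list[np.ndarray]  # per-ROI event amplitudes (full-length trains)
    ar_order: int = 2


# ---------------------------------------------------------------------------
# segmentation

class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def segment_ground_truth(
    footprints: dict[int, np.ndarray],
    min_px: int = 5,
    overlap_frac: float = 0.8,
) -> ROISet:
    """Prune small footprints, then transitively merge highly overlapping ones.

    Overlap between two ROIs is the shared pixel count divided by the pixel
    count of the smaller ROI; pairs exceeding ``overlap_frac`` are linked and
    linked groups merged (union of pixels and of source neuron ids). The
    result does not depend on the order footprints are examined.
    """
    if min_px < 1:
        raise ValueError("min_px must be >= 1")
    if not (0.0 < overlap_frac <= 1.0):
        raise ValueError("overlap_frac must be in (0, 1]")
    items = [(int(nid), np.unique(np.asarray(px, dtype=np.int64)))
             for nid, px in sorted(footprints.items())]
    items = [(nid, px) for nid, px in items if len(px) >= min_px]
    if not items:
        return ROISet()

    n = len(items)
    uf = _UnionFind(n)
    sets = [set(px.tolist()) for _, px in items]
    for i in range(n):
        for j in range(i + 1, n):
            shared = len(sets[i] & sets[j])
            if shared == 0:
                continue
            if shared / min(len(sets[i]), len(sets[j])) > overlap_frac:
                uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    rois = []
    for members in groups.values():
        px = np.unique(np.concatenate([items[i][1] for i in members]))
        ids = tuple(sorted(items[i][0] for i in members))
        rois.append(ROI(pixels=px, source_neuron_ids=ids))
    rois.sort(key=lambda r: r.source_neuron_ids)
    return ROISet(rois)


# ---------------------------------------------------------------------------
# peak-SNR

def peak_snr(trace: np.ndarray, peak_halfwidth: int = 1) -> float:
    """(peak - baseline mean) / baseline sd.

    The baseline is the part of the trace below its 25th percentile; the peak
    is the maximum within ``peak_halfwidth`` frames of the global maximum.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 8:
        raise ValueError("trace too short for peak-SNR")
    q25 = np.percentile(x, 25)
    base = x[x < q25]
    if base.size == 0 or base.std() == 0:
        raise ValueError("peak-SNR undefined: constant baseline")
    t = int(np.argmax(x))
    lo, hi = max(t - peak_halfwidth, 0), min(t + peak_halfwidth + 1, x.size)
    return float((x[lo:hi].max() - base.mean()) / base.std())


def filter_by_peak_snr(rois: ROISet, threshold: float) -> ROISet:
    """Keep ROIs whose peak-SNR exceeds ``threshold`` (monotone in threshold)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    kept = [r for r in rois if r.peak_snr is not None and r.peak_snr > threshold]
    return ROISet(kept)


# ---------------------------------------------------------------------------
# trace extraction

def extract_trace(frames_flat: np.ndarray, roi: ROI) -> np.ndarray:
    """Mean trace over a greedily selected pixel subset of the ROI.

    Pixels are ranked by individual peak-SNR and added one by one while the
    peak-SNR of the running mean trace keeps increasing; this mimics picking
    only the pixels that maximize the quality of the extracted signal.
    ``frames_flat`` is (n_frames, n_pixels_total).
    """
    traces = frames_flat[:, roi.pixels].astype(float)  # (n_frames, n_px)
    n_px = traces.shape[1]
    if n_px == 1:
        return traces[:, 0]

    def safe_snr(x):
        try:
            return peak_snr(x)
        except ValueError:
            return -np.inf

    order = np.argsort([-safe_snr(traces[:, j]) for j in range(n_px)])
    best = traces[:, order[0]].copy()
    best_snr = safe_snr(best)
    csum = best.copy()
    k = 1
    for j in order[1:]:
        cand = (csum + traces[:, j]) / (k + 1)
        s = safe_snr(cand)
        if s > best_snr:
            best, best_snr = cand, s
            csum = csum + traces[:, j]
            k += 1
        else:
            break
    return best


# ---------------------------------------------------------------------------
# deconvolution

def _estimate_noise_sd(x: np.ndarray) -> float:
    """Noise level from the high-frequency half of the power spectrum."""
    n = len(x)
    nper = min(256, n)
    f, p = welch(x, nperseg=nper)
    half = p[f > 0.25]
    if half.size == 0:
        half = p
    return float(np.sqrt(np.median(half) / 2.0 * 1.0))


def _estimate_ar_coeffs(x: np.ndarray, order: int, noise_sd: float) -> np.ndarray:
    """Yule-Walker AR coefficients with the lag-0 term noise-corrected."""
    x = x - x.mean()
    n = len(x)
    lags = order + 1
    acov = np.array([np.dot(x[: n - k], x[k:]) / n for k in range(lags + order)])
    acov[0] = max(acov[0] - noise_sd**2, 1e-12)
    A = np.empty((order, order))
    for i in range(order):
        for j in range(order):
            A[i, j] = acov[abs(i - j)]
    b = acov[1 : order + 1]
    try:
        g = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        g = np.zeros(order)
        g[0] = 0.9
    # keep the AR polynomial stable
    roots = np.roots(np.concatenate([[1.0], -g]))
    if np.any(np.abs(roots) >= 1.0):
        roots = np.clip(np.abs(roots), 0, 0.98) * np.sign(roots.real + 1e-12)
        poly = np.poly(roots)
        g = -poly[1:]
    return g


def _ar_kernel(g: np.ndarray, n: int) -> np.ndarray:
    """Impulse response of 1 / (1 - g1 B - g2 B^2 - ...)."""
    h = np.zeros(n)
    h[0] = 1.0
    for t in range(1, n):
        for k, gk in enumerate(g, start=1):
            if t - k >= 0:
                h[t] += gk * h[t - k]
    return h


def deconvolve(
    F_raw: np.ndarray,
    frame_rate: float,
    g: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse non-negative deconvolution under an AR model.

    The AR order is 1 below 2 Hz and 2 otherwise; coefficients are estimated
    from the trace autocovariance unless supplied. Returns the denoised
    calcium ``Cdf = h * s`` and the event train ``s`` (non-negative least
    squares on the AR impulse-response convolution matrix).
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    x = np.asarray(F_raw, dtype=float)
    n = x.size
    if n < 4 or np.ptp(x) == 0:
        return np.zeros(n), np.zeros(n)
    order = 1 if frame_rate < 2.0 else 2
    noise_sd = _estimate_noise_sd(x)
    if g is None:
        g = _estimate_ar_coeffs(x, order, noise_sd)
    g = np.atleast_1d(np.asarray(g, dtype=float))

    q25 = np.percentile(x, 25)
    low = x[x <= q25]
    baseline = float(low.mean()) if low.size else float(x.min())
    y = x - baseline
    h = _ar_kernel(g, n)
    Hm = np.zeros((n, n))
    for j in range(n):
        Hm[j:, j] = h[: n - j]
    s, _ = nnls(Hm, y, maxiter=10 * n)
    if s.max() > 0:
        s[s < 1e-8 * s.max()] = 0.0  # numerical dust
    cdf = Hm @ s
    return cdf, s


# ---------------------------------------------------------------------------
# pipeline convenience

def segment_and_extract(
    tseries,
    min_px: int = 5,
    overlap_frac: float = 0.8,
    snr_threshold: float | None = 20.0,
    deconvolve_traces: bool = True,
) -> tuple[ROISet, TraceSet | None]:
    """Full segmentation pipeline on a rendered TSeries.

    Builds ground-truth footprints from provenance, prunes/merges, extracts
    greedy-subset traces, computes peak-SNR, filters at ``snr_threshold``
    (skipped when None), and deconvolves the surviving traces.
    """
    frames_flat = tseries.frames.reshape(tseries.n_frames, -1)
    rois = segment_ground_truth(tseries.footprints(), min_px, overlap_frac)
    H, W = tseries.shape
    posx = tseries.pixel_pos_um[..., 0].ravel()
    posy = tseries.pixel_pos_um[..., 1].ravel()
    kept = []
    for roi in rois:
        roi.trace = extract_trace(frames_flat, roi)
        try:
            roi.peak_snr = peak_snr(roi.trace)
        except ValueError:
            continue
        cxu = float(posx[roi.pixels].mean())
        cyu = float(posy[roi.pixels].mean())
        roi.centroid_um = (cxu, cyu)
        roi.dist_r_um = float(np.hypot(cxu, cyu))
        kept.append(roi)
    rois = ROISet(kept)
    if snr_threshold is not None:
        rois = filter_by_peak_snr(rois, snr_threshold)
    if not deconvolve_traces or len(rois) == 0:
        return rois, None
    raw = np.stack([r.trace for r in rois])
    cdfs = np.empty_like(raw)
    events = []
    for i in range(raw.shape[0]):
        cdf, s = deconvolve(raw[i], tseries.frame_rate)
        cdfs[i] = cdf
        events.append(s)
    order = 1 if tseries.frame_rate < 2.0 else 2
    return rois, TraceSet(raw=raw, calcium=cdfs, events=events, ar_order=order)
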