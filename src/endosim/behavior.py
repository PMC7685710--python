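"""Behavioral-state classification from whisker, wheel, and pupil traces.

States per imaging frame: quiet (Q), whisking-only (W), locomotion-only (L),
and whisking+locomotion (WL); the "active" state A is W ∪ WL. Whisking is
detected from the smoothed moving standard deviation of the whisker mean
angle with a ROC-calibrated amplitude threshold; locomotion from a
three-condition wheel-speed criterion; pupil diameter from an ellipse fit of
the Otsu-thresholded dark region of each eye frame.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, filtfilt
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "whisking_envelope",
    "detect_whisking",
    "detect_locomotion",
    "pupil_diameter",
    "classify_states",
    "state_pupil_distribution",
    "intervals_to_mask",
    "mask_to_intervals",
]


def mask_to_intervals(mask: np.ndarray, fs: float) -> list[tuple[float, float]]:
    """Boolean sample mask -> list of (start_s, end_s) intervals."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    d = np.diff(m.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        ends = np.r_[ends, m.size]
    return [(s / fs, e / fs) for s, e in zip(starts, ends)]


def intervals_to_mask(intervals, fs: float, n: int) -> np.ndarray:
    m = np.zeros(n, dtype=bool)
    for s, e in intervals:
        m[int(np.floor(s * fs)) : int(np.ceil(e * fs))] = True
    return m


def _bridge_short_gaps(mask: np.ndarray, fs: float, max_gap_s: float) -> np.ndarray:
    m = np.asarray(mask, dtype=bool).copy()
    inv = ~m
    d = np.diff(inv.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if inv[0]:
        starts = np.r_[0, starts]
    if inv[-1]:
        ends = np.r_[ends, inv.size]
    for s, e in zip(starts, ends):
        interior = s > 0 and e < m.size  # only gaps between active periods
        if interior and (e - s) / fs < max_gap_s:
            m[s:e] = True
    return m


def _drop_short_runs(mask: np.ndarray, fs: float, min_dur_s: float) -> np.ndarray:
    m = np.asarray(mask, dtype=bool).copy()
    d = np.diff(m.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        ends = np.r_[ends, m.size]
    for s, e in zip(starts, ends):
        if (e - s) / fs < min_dur_s:
            m[s:e] = False
    return m


def whisking_envelope(angle: np.ndarray, fs: float = 150.0,
                      sd_window_s: float = 0.4, gauss_window_s: float = 0.05) -> np.ndarray:
    """Centered moving standard deviation, Gaussian smoothed.

    The Gaussian sigma is half the stated smoothing window.
    """
    s = pd.Series(np.asarray(angle, dtype=float))
    win = max(int(round(sd_window_s * fs)), 2)
    mov_sd = s.rolling(win, center=True, min_periods=1).std(ddof=0).to_numpy()
    sigma = max(gauss_window_s * fs / 2.0, 1e-6)
    return gaussian_filter1d(mov_sd, sigma)


def detect_whisking(
    angle_trace: np.ndarray,
    labeled_subset: tuple[np.ndarray, np.ndarray] | None = None,
    fs: float = 150.0,
    threshold: float | None = None,
    min_duration_s: float = 0.2,
    max_gap_s: float = 0.5,
) -> list[tuple[float, float]]:
    """Whisking intervals from a whisker mean-angle trace.

    The amplitude threshold on the envelope is chosen by ROC analysis
    (maximizing Youden's J) against a manually labeled subset given as
    ``(sample_indices, binary_labels)``; alternatively pass ``threshold``
    directly. Events shorter than 200 ms are discarded and gaps shorter than
    0.5 s bridged. NaN samples are linearly interpolated first.
    """
    x = np.asarray(angle_trace, dtype=float)
    if np.any(np.isnan(x)):
        idx = np.arange(x.size)
        good = ~np.isnan(x)
        x = np.interp(idx, idx[good], x[good])
    env = whisking_envelope(x, fs)
    if threshold is None:
        if labeled_subset is None:
            raise ValueError("need a labeled subset or an explicit threshold")
        sub_idx, sub_lab = labeled_subset
        sub_idx = np.asarray(sub_idx, dtype=int)
        sub_lab = np.asarray(sub_lab, dtype=bool)
        threshold = roc_threshold(env[sub_idx], sub_lab)
    mask = env > threshold
    mask = _bridge_short_gaps(mask, fs, max_gap_s)
    mask = _drop_short_runs(mask, fs, min_duration_s)
    return mask_to_intervals(mask, fs)


def roc_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing Youden's J (TPR - FPR) over candidate cuts."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        return float(np.median(scores))
    cuts = np.unique(scores)
    best_j, best_t = -np.inf, float(cuts[0])
    pos, neg = labels.sum(), (~labels).sum()
    for t in cuts:
        pred = scores > t
        tpr = np.sum(pred & labels) / pos
        fpr = np.sum(pred & ~labels) / neg
        j = tpr - fpr
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def detect_locomotion(
    speed_trace: np.ndarray,
    fs: float = 40.0,
    instant_thresh: float = 1.0,
    lowpass_hz: float = 0.25,
    lowpass_thresh: float = 1.0,
    window_s: float = 2.0,
    window_thresh: float = 0.1,
    max_gap_s: float = 0.5,
) -> list[tuple[float, float]]:
    """Locomotion intervals from wheel speed (cm/s, resampled to 40 Hz).

    A sample is locomotion iff (i) instantaneous speed > 1 cm/s, (ii) 0.25 Hz
    low-pass filtered speed > 1 cm/s, and (iii) mean speed over a 2 s window
    > 0.1 cm/s; gaps shorter than 0.5 s are merged.
    """
    v = np.asarray(speed_trace, dtype=float)
    if v.size == 0:
        return []
    nyq = fs / 2.0
    b, a = butter(2, lowpass_hz / nyq, btype="low")
    pad = min(3 * max(len(a), len(b)), v.size - 1)
    v_lp = filtfilt(b, a, v, padlen=pad) if v.size > pad else v
    win = max(int(round(window_s * fs)), 1)
    v_avg = pd.Series(v).rolling(win, center=True, min_periods=1).mean().to_numpy()
    mask = (v > instant_thresh) & (v_lp > lowpass_thresh) & (v_avg > window_thresh)
    mask = _bridge_short_gaps(mask, fs, max_gap_s)
    return mask_to_intervals(mask, fs)


def pupil_diameter(eye_frames: np.ndarray) -> np.ndarray:
    """Pupil diameter per frame: major axis of an ellipse fitted to the
    largest dark region after Otsu thresholding; failed frames are linearly
    interpolated from their neighbors."""
    frames = np.asarray(eye_frames, dtype=float)
    out = np.full(frames.shape[0], np.nan)
    for i, fr in enumerate(frames):
        if np.ptp(fr) == 0:
            continue
        thr = threshold_otsu(fr)
        dark = fr < thr
        if not dark.any():
            continue
        lab = label(dark)
        props = regionprops(lab)
        biggest = max(props, key=lambda p: p.area)
        out[i] = biggest.axis_major_length
    if np.isnan(out).all():
        raise ValueError("no pupil detected in any frame")
    idx = np.arange(out.size)
    good = ~np.isnan(out)
    return np.interp(idx, idx[good], out[good])


def classify_states(
    whisking: list[tuple[float, float]],
    locomotion: list[tuple[float, float]],
    frame_times_s: np.ndarray,
    frame_duration_s: float | None = None,
    coverage: float = 0.5,
) -> np.ndarray:
    """Per-imaging-frame labels in {"Q", "W", "L", "WL"}.

    A frame inherits a behavior when the behavior covers more than
    ``coverage`` of its exposure window.
    """
    t = np.asarray(frame_times_s, dtype=float)
    if frame_duration_s is None:
        frame_duration_s = float(np.median(np.diff(t))) if t.size > 1 else 1.0

    def frac_covered(intervals):
        out = np.zeros(t.size)
        for s, e in intervals:
            lo = np.maximum(t, s)
            hi = np.minimum(t + frame_duration_s, e)
            out += np.maximum(hi - lo, 0.0)
        return out / frame_duration_s

    w = frac_covered(whisking) > coverage
    l = frac_covered(locomotion) > coverage
    labels = np.full(t.size, "Q", dtype=object)
    labels[w & ~l] = "W"
    labels[~w & l] = "L"
    labels[w & l] = "WL"
    return labels


def state_pupil_distribution(
    pupil: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Normalized per-state histograms of pupil size over common bins.

    Returns (histograms, bin_edges); states with no frames map to an all-NaN
    histogram (flagged absent).
    """
    pupil = np.asarray(pupil, dtype=float)
    labels = np.asarray(labels)
    if pupil.size != labels.size:
        raise ValueError("pupil and labels must be aligned")
    edges = np.linspace(pupil.min(), pupil.max(), n_bins + 1)
    hists = {}
    for st in ("Q", "W", "L", "WL"):
        sel = pupil[labels == st]
        if sel.size == 0:
            hists[st] = np.full(n_bins, np.nan)
            continue
        h, _ = np.histogram(sel, bins=edges)
        hists[st] = h / h.sum()
    return hists, edges
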