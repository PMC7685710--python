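"""Mutual information about a binary behavioral state in single ROIs, pairs
(synergy/redundancy), and populations (SVM decoding), with
quadratic-extrapolation bias correction and balanced resampling.

Direct-method recipe: responses are discretized into equipopulated bins,
plug-in MI is computed on the full sample and on random halves and quarters,
and a quadratic in inverse sample size is extrapolated to infinite data to
remove the limited-sampling bias. State sampling is balanced (the number of
time points of the rarer state drawn from each state) so state prevalence
does not masquerade as information. All information values are in bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "InfoEstimate",
    "InfoDistributionFit",
    "discretize",
    "plugin_mi",
    "mi_direct",
    "balanced_mi",
    "fit_info_distribution",
    "pair_co_information",
    "svm_decoding_info",
    "radius_pooling_curve",
    "confusion_matrix_information",
]


@dataclass
class InfoEstimate:
    mi: float  # bits
    significant: bool
    shuffle_null: np.ndarray
    n_iterations: int
    unstable: bool = False


@dataclass
class InfoDistributionFit:
    a: float
    b: float
    c: float
    d: float
    r_squared: float
    converged: bool


# ---------------------------------------------------------------------------
# discretization and plug-in MI

def discretize(responses: np.ndarray, n_bins: int = 2) -> np.ndarray:
    """Equipopulated binning (median split for two bins)."""
    x = np.asarray(responses, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    # ties at a bin edge go to the lower bin (so a median split of
    # zero-inflated responses separates zeros from the rest); if that empties
    # every bin but one on non-constant data, send ties up instead
    out = np.digitize(x, qs, right=True)
    if np.ptp(x) > 0 and len(np.unique(out)) == 1:
        out = np.digitize(x, qs, right=False)
    return out


def plugin_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI (bits) between two discrete variables."""
    x = np.asarray(x)
    y = np.asarray(y)
    xs, xi = np.unique(x, return_inverse=True)
    ys, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((len(xs), len(ys)))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log2(joint / (px * py))
    return float(np.nansum(term))


def _qe_corrected(x_disc: np.ndarray, y: np.ndarray,
                  rng: np.random.Generator) -> float:
    """Quadratic-extrapolation bias correction of the plug-in MI.

    MI is estimated on the full sample, on 2 random halves, and on 4 random
    quarters (averaged per fraction); a quadratic in 1/N through the three
    points is extrapolated to 1/N -> 0.
    """
    n = len(y)
    i_full = plugin_mi(x_disc, y)
    perm = rng.permutation(n)
    halves = [perm[: n // 2], perm[n // 2 : 2 * (n // 2)]]
    i_half = float(np.mean([plugin_mi(x_disc[h], y[h]) for h in halves]))
    quarters = [perm[k * (n // 4) : (k + 1) * (n // 4)] for k in range(4)]
    i_quarter = float(np.mean([plugin_mi(x_disc[q], y[q]) for q in quarters]))
    xs = np.array([1.0 / n, 2.0 / n, 4.0 / n])
    ys = np.array([i_full, i_half, i_quarter])
    coef = np.polyfit(xs, ys, 2)
    return float(coef[-1])


def mi_direct(
    responses: np.ndarray,
    states: np.ndarray,
    n_bins: int = 2,
    bias: str = "qe",
    rng: np.random.Generator | None = None,
    discretized: bool = False,
) -> float:
    """Bias-corrected MI (bits) between a scalar response and a binary state.

    ``discretized=True`` treats ``responses`` as already-binned symbols (used
    for joint pair responses). The corrected estimate is clamped at zero.
    """
    states = np.asarray(states)
    if len(np.unique(states)) < 2:
        raise ValueError("both states must be present")
    rng = np.random.default_rng() if rng is None else rng
    x = np.asarray(responses) if discretized else discretize(responses, n_bins)
    if bias == "qe":
        mi = _qe_corrected(x, states, rng)
    elif bias in (None, "none"):
        mi = plugin_mi(x, states)
    else:
        raise ValueError(f"unknown bias correction: {bias!r}")
    return max(mi, 0.0)


# ---------------------------------------------------------------------------
# balanced single-ROI information

def _balanced_indices(states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    vals = np.unique(states)
    n_t = min(int(np.sum(states == v)) for v in vals)
    idx = np.concatenate([
        rng.choice(np.flatnonzero(states == v), n_t, replace=False) for v in vals
    ])
    return idx


def balanced_mi(
    roi_trace: np.ndarray,
    state_labels: np.ndarray,
    n_iter: int = 100,
    n_shuffle: int = 500,
    rng: np.random.Generator | None = None,
    n_bins: int = 2,
) -> InfoEstimate:
    """State information of one ROI with balanced resampling and a shuffle null.

    Per iteration, n_T time points per state (n_T = occupancy of the rarer
    state) are sampled without replacement and the QE-corrected MI computed;
    the estimate is the mean over iterations. Significance: the mean exceeds
    the 95th percentile of ``n_shuffle`` label-shuffled estimates obtained
    with the same estimator settings.
    """
    rng = np.random.default_rng() if rng is None else rng
    x = np.asarray(roi_trace, dtype=float)
    s = np.asarray(state_labels)
    if len(np.unique(s)) < 2:
        raise ValueError("both states must be present")
    n_t = min(int(np.sum(s == v)) for v in np.unique(s))
    unstable = n_t < 10
    if unstable:
        warnings.warn(f"only {n_t} time points in the rarer state; "
                      "estimate flagged unstable", stacklevel=2)

    vals = []
    for _ in range(n_iter):
        idx = _balanced_indices(s, rng)
        vals.append(mi_direct(x[idx], s[idx], n_bins=n_bins, rng=rng))
    mi = float(np.mean(vals))

    null = np.empty(n_shuffle)
    for k in range(n_shuffle):
        s_sh = rng.permutation(s)
        idx = _balanced_indices(s_sh, rng)
        null[k] = mi_direct(x[idx], s_sh[idx], n_bins=n_bins, rng=rng)
    significant = mi > np.percentile(null, 95)
    return InfoEstimate(mi=mi, significant=bool(significant), shuffle_null=null,
                        n_iterations=n_iter, unstable=unstable)


# ---------------------------------------------------------------------------
# population information distribution

def _dexp(i, a, b, c, d):
    return a * np.exp(-b * i) + c * np.exp(-d * i)


def fit_info_distribution(sorted_infos: np.ndarray) -> InfoDistributionFit:
    """Double-exponential fit of descending-sorted per-ROI information.

    I(i) = a e^(-b i) + c e^(-d i) over the 1-based rank i. Non-convergence
    falls back to a single exponential (reported with c = d = 0 and
    ``converged=False``).
    """
    y = np.asarray(sorted_infos, dtype=float)
    if y.size < 8:
        raise ValueError("need at least 8 ROIs")
    if np.any(np.diff(y) > 1e-12):
        y = np.sort(y)[::-1]
    if np.ptp(y) < 1e-12:
        # all-equal information values: decay rates degenerate to zero
        return InfoDistributionFit(a=float(y[0] / 2), b=0.0, c=float(y[0] / 2),
                                   d=0.0, r_squared=np.nan, converged=False)
    i = np.arange(1, y.size + 1, dtype=float)
    a0 = max(y[0], 1e-6)
    b0 = 1.0 / max(y.size / 4.0, 1.0)
    try:
        p, _ = curve_fit(_dexp, i, y, p0=(a0 * 0.7, b0 * 3, a0 * 0.3, b0 / 3),
                         maxfev=20000)
        fit = _dexp(i, *p)
        converged = True
    except RuntimeError:
        single = lambda i_, a, b: a * np.exp(-b * i_)
        p1, _ = curve_fit(single, i, y, p0=(a0, b0), maxfev=20000)
        p = (p1[0], p1[1], 0.0, 0.0)
        fit = single(i, *p1)
        converged = False
    ss_res = float(np.sum((y - fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return InfoDistributionFit(a=float(p[0]), b=float(p[1]), c=float(p[2]),
                               d=float(p[3]), r_squared=r2, converged=converged)


# ---------------------------------------------------------------------------
# pairwise synergy / redundancy

def pair_co_information(
    r1: np.ndarray,
    r2: np.ndarray,
    states: np.ndarray,
    n_perm: int = 500,
    rng: np.random.Generator | None = None,
    n_bins: int = 2,
) -> tuple[float, str, bool]:
    """Co-information of a response pair: I(S;R1,R2) - I(S;R1) - I(S;R2).

    Each term is QE bias-corrected and permutation-subtracted using the same
    ``n_perm`` label permutations; positive values mean synergy, negative
    redundancy. Significance: the observed co-information lies outside the
    central 95% of the permutation null.
    """
    rng = np.random.default_rng() if rng is None else rng
    s = np.asarray(states)
    if len(np.unique(s)) < 2:
        raise ValueError("both states must be present")
    b1 = discretize(np.asarray(r1, dtype=float), n_bins)
    b2 = discretize(np.asarray(r2, dtype=float), n_bins)
    joint = b1 * n_bins + b2

    def delta(labels):
        i12 = mi_direct(joint, labels, discretized=True, rng=rng)
        i1 = mi_direct(b1, labels, discretized=True, rng=rng)
        i2 = mi_direct(b2, labels, discretized=True, rng=rng)
        return i12 - i1 - i2

    observed = delta(s)
    null = np.array([delta(rng.permutation(s)) for _ in range(n_perm)])
    corrected = observed - float(null.mean())
    lo, hi = np.percentile(null, [2.5, 97.5])
    significant = bool(observed < lo or observed > hi)
    cls = "synergy" if corrected > 0 else "redundancy"
    return corrected, cls, significant


# ---------------------------------------------------------------------------
# population decoding

def confusion_matrix_information(cm: np.ndarray) -> float:
    """MI (bits) of the joint distribution a normalized confusion matrix defines."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total == 0:
        return 0.0
    joint = cm / total
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log2(joint / (px * py))
    return float(np.nansum(term))


def svm_decoding_info(
    population_responses: np.ndarray,
    states: np.ndarray,
    n_iter: int = 100,
    rng: np.random.Generator | None = None,
    param_grid: dict | None = None,
    cv_folds: int = 10,
) -> float:
    """State information decoded from population activity by an RBF SVM.

    Per iteration, a balanced sample (n_T per state) is split into equal
    train/test halves; SVM hyperparameters are selected by cross-validated
    grid search on the train half, and the test-half confusion matrix is
    converted to mutual information. Returns the mean over iterations.
    """
    X = np.atleast_2d(np.asarray(population_responses, dtype=float))
    s = np.asarray(states)
    if X.shape[0] != s.size:
        X = X.T
    if len(np.unique(s)) < 2:
        raise ValueError("both states must be present")
    rng = np.random.default_rng() if rng is None else rng
    if param_grid is None:
        param_grid = {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 0.1, 1.0]}

    vals = []
    for _ in range(n_iter):
        idx = _balanced_indices(s, rng)
        rng.shuffle(idx)
        y = (s[idx] == np.unique(s)[1]).astype(int)
        # balanced half split per class
        tr, te = [], []
        for cls in (0, 1):
            cls_idx = np.flatnonzero(y == cls)
            half = len(cls_idx) // 2
            tr.extend(cls_idx[:half])
            te.extend(cls_idx[half:])
        tr = np.array(tr)
        te = np.array(te)
        folds = min(cv_folds, int(np.bincount(y[tr]).min()))
        if folds < 2:
            continue
        search = GridSearchCV(
            SVC(kernel="rbf"), param_grid,
            cv=StratifiedKFold(folds, shuffle=True,
                               random_state=int(rng.integers(2**31))),
            n_jobs=1,
        )
        search.fit(X[idx][tr], y[tr])
        pred = search.predict(X[idx][te])
        cm = np.zeros((2, 2))
        np.add.at(cm, (y[te], pred), 1.0)
        vals.append(confusion_matrix_information(cm))
    return float(np.mean(vals)) if vals else 0.0


def radius_pooling_curve(
    roi_dist_r: np.ndarray,
    population_responses: np.ndarray,
    states: np.ndarray,
    fov_radius_um: float = 250.0,
    n_steps: int = 4,
    n_iter: int = 20,
    rng: np.random.Generator | None = None,
    param_grid: dict | None = None,
    cv_folds: int = 10,
) -> list[dict]:
    """Decoding MI for populations within growing inclusion radii.

    ROIs within 1/4, 2/4, ... of the FOV radius are incrementally pooled; an
    empty step carries the previous value forward and is flagged.
    """
    rng = np.random.default_rng() if rng is None else rng
    d = np.asarray(roi_dist_r, dtype=float)
    X = np.atleast_2d(np.asarray(population_responses, dtype=float))
    if X.shape[1] != d.size and X.shape[0] == d.size:
        X = X.T  # -> (n_samples, n_rois)
    out = []
    prev = 0.0
    for k in range(1, n_steps + 1):
        radius = k * fov_radius_um / n_steps
        sel = d < radius
        if not sel.any():
            out.append(dict(radius_um=radius, n_rois=0, mi_bits=prev, empty=True))
            continue
        mi = svm_decoding_info(X[:, sel], states, n_iter=n_iter, rng=rng,
                               param_grid=param_grid, cv_folds=cv_folds)
        prev = mi
        out.append(dict(radius_um=radius, n_rois=int(sel.sum()), mi_bits=mi,
                        empty=False))
    return out
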