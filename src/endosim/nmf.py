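"""Neuronal-ensemble identification by non-negative matrix factorization,
with module metrics (sparseness, whisking modulation, spatial spread),
similarity indices, and shuffle nulls.

The ROI-by-time activity matrix is factorized as W·H with nonnegative
factors; each module pairs ROI weights (a column of W) with a time-varying
activation coefficient (a row of H). The module count is chosen by the
ability of an LDA classifier on the reduced data to predict the behavioral
state, stopping at the first elbow of the performance curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from sklearn.decomposition import NMF
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import balanced_accuracy_score

__all__ = [
    "ModuleSet",
    "select_k",
    "factorize",
    "module_metrics",
    "module_similarity",
    "shuffle_null",
    "sparseness",
    "whisking_modulation_index",
    "spatial_spread",
]


@dataclass
class ModuleSet:
    """NMF factors: W (ROI x module weights) and H (module x time activations)."""

    W: np.ndarray
    H: np.ndarray
    k: int
    reconstruction_error: float = np.nan
    metrics: list[dict] = field(default_factory=list)

    @property
    def n_rois(self) -> int:
        return self.W.shape[0]


def _nmf_fit(data: np.ndarray, k: int, seed: int, max_iter: int = 500):
    model = NMF(n_components=k, init="nndsvda" if k <= min(data.shape) else "random",
                random_state=seed, max_iter=max_iter)
    W = model.fit_transform(data)
    return W, model.components_, model.reconstruction_err_


def factorize(
    data: np.ndarray,
    k: int,
    rng: np.random.Generator | None = None,
    n_restarts: int = 3,
) -> ModuleSet:
    """Multi-restart NMF of a nonnegative ROI-by-time matrix; best fit kept."""
    data = np.asarray(data, dtype=float)
    if np.any(data < 0):
        raise ValueError("data must be non-negative (rectify before factorizing)")
    if not (1 <= k <= data.shape[0]):
        raise ValueError("k must be in [1, n_rois]")
    rng = np.random.default_rng() if rng is None else rng
    best = None
    for _ in range(n_restarts):
        seed = int(rng.integers(2**31))
        W, H, err = _nmf_fit(data, k, seed)
        if best is None or err < best[2]:
            best = (W, H, err)
    return ModuleSet(W=best[0], H=best[1], k=k, reconstruction_error=best[2])


def select_k(
    train_data: np.ndarray,
    test_data: np.ndarray,
    train_labels: np.ndarray,
    test_labels: np.ndarray,
    k_max: int | None = None,
    elbow_gain: float = 0.004,
    rng: np.random.Generator | None = None,
) -> tuple[int, np.ndarray]:
    """Module count by LDA decodability of the state from reduced data.

    For each k, the train half is factorized, both halves are projected onto
    the module activations (nonnegative least squares via the transform of
    the fitted NMF), an LDA is trained on the train activations and scored
    (balanced accuracy) on the test half. Returns the first k whose
    successor improves performance by less than ``elbow_gain`` (0.4
    percentage points), plus the full performance curve; if the curve never
    flattens the maximum k is returned.
    """
    train_data = np.asarray(train_data, dtype=float)
    test_data = np.asarray(test_data, dtype=float)
    rng = np.random.default_rng() if rng is None else rng
    n_rois = train_data.shape[0]
    k_max = n_rois if k_max is None else min(k_max, n_rois)
    perf = np.zeros(k_max)
    for k in range(1, k_max + 1):
        seed = int(rng.integers(2**31))
        W, Htr, _ = _nmf_fit(train_data, k, seed, max_iter=400)
        Hte = _project_activations(W, test_data)
        lda = LinearDiscriminantAnalysis()
        try:
            lda.fit(Htr.T, np.asarray(train_labels))
            pred = lda.predict(Hte.T)
            perf[k - 1] = balanced_accuracy_score(np.asarray(test_labels), pred)
        except Exception:
            perf[k - 1] = 0.5
        if k >= 2 and perf[k - 1] - perf[k - 2] < elbow_gain:
            return k - 1, perf[:k]
    return k_max, perf


def _project_activations(W: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Activations H >= 0 solving data ≈ W·H with the ROI basis W fixed
    (non-negative least squares per frame)."""
    from scipy.optimize import nnls

    n_frames = data.shape[1]
    H = np.zeros((W.shape[1], n_frames))
    for t in range(n_frames):
        H[:, t], _ = nnls(W, data[:, t])
    return H


def module_metrics(
    weights: np.ndarray,
    activations: np.ndarray,
    labels: np.ndarray,
    roi_positions: np.ndarray,
    top_n: int = 10,
) -> dict:
    """Sparseness, whisking modulation index, and spatial spread of a module."""
    w = np.asarray(weights, dtype=float)
    if np.all(w == 0):
        raise ValueError("all-zero module weights")
    return dict(
        sparseness=sparseness(w),
        wmi=whisking_modulation_index(activations, labels),
        spatial_spread=spatial_spread(w, roi_positions, top_n=top_n),
    )


def sparseness(weights: np.ndarray) -> float:
    """Participation-ratio sparseness: sum(w^2) / (sum(w))^2.

    1 when a single ROI carries all the weight; 1/n for n equal weights.
    """
    w = np.asarray(weights, dtype=float)
    s = w.sum()
    if s == 0:
        raise ValueError("all-zero weights")
    return float(np.sum(w**2) / s**2)


def whisking_modulation_index(activations: np.ndarray, labels: np.ndarray) -> float:
    """(mean act_A - mean act_Q) / (mean act_A + mean act_Q), in [-1, 1]."""
    act = np.asarray(activations, dtype=float)
    lab = np.asarray(labels)
    a = act[lab == 1].mean() if np.any(lab == 1) else np.nan
    q = act[lab == 0].mean() if np.any(lab == 0) else np.nan
    if np.isnan(a) or np.isnan(q):
        raise ValueError("labels must contain both states")
    denom = a + q
    return float((a - q) / denom) if denom > 0 else 0.0


def _path_dp(dist: np.ndarray) -> float:
    """Exact shortest open path visiting all nodes (Held-Karp subset DP)."""
    n = dist.shape[0]
    if n <= 1:
        return 0.0
    full = 1 << n
    dp = np.full((full, n), np.inf)
    for i in range(n):
        dp[1 << i, i] = 0.0
    for mask in range(full):
        for last in range(n):
            cur = dp[mask, last]
            if not np.isfinite(cur):
                continue
            for nxt in range(n):
                if mask & (1 << nxt):
                    continue
                nm = mask | (1 << nxt)
                cand = cur + dist[last, nxt]
                if cand < dp[nm, nxt]:
                    dp[nm, nxt] = cand
    return float(dp[full - 1].min())


def spatial_spread_brute(points: np.ndarray) -> float:
    """Brute-force shortest open path (for cross-checking the DP, n <= 8)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n <= 1:
        return 0.0
    best = np.inf
    for perm in permutations(range(n)):
        if perm[0] > perm[-1]:
            continue  # path direction is irrelevant
        d = sum(np.linalg.norm(pts[perm[i + 1]] - pts[perm[i]])
                for i in range(n - 1))
        best = min(best, d)
    return float(best)


def spatial_spread(weights: np.ndarray, roi_positions: np.ndarray,
                   top_n: int = 10) -> float:
    """Length (µm) of the shortest open path connecting the ``top_n``
    highest-weight ROIs (all ROIs if fewer), solved exactly by subset DP."""
    w = np.asarray(weights, dtype=float)
    pos = np.asarray(roi_positions, dtype=float)
    idx = np.argsort(-w)[: min(top_n, np.count_nonzero(w) or 1)]
    pts = pos[idx]
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return _path_dp(d)


def module_membership(weights: np.ndarray, eps_frac: float = 1e-6) -> np.ndarray:
    """Binary membership: weight above ``eps_frac`` of the module's maximum."""
    w = np.asarray(weights, dtype=float)
    if w.max() == 0:
        return np.zeros_like(w, dtype=bool)
    return w > eps_frac * w.max()


def module_similarity(w1: np.ndarray, w2: np.ndarray) -> dict:
    """Jaccard index of memberships and cosine similarity of weight vectors."""
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    m1 = module_membership(w1)
    m2 = module_membership(w2)
    union = np.sum(m1 | m2)
    jac = float(np.sum(m1 & m2) / union) if union else 0.0
    n1, n2 = np.linalg.norm(w1), np.linalg.norm(w2)
    cos = float(np.dot(w1, w2) / (n1 * n2)) if n1 > 0 and n2 > 0 else 0.0
    return dict(jaccard=jac, cosine=cos)


def shuffle_null(
    module_set: ModuleSet,
    roi_positions: np.ndarray,
    labels: np.ndarray,
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
) -> dict:
    """Null distributions for similarity (weight shuffles) and spatial spread
    (ROI-position shuffles); single-ROI modules are excluded."""
    rng = np.random.default_rng() if rng is None else rng
    W = module_set.W
    multi = [i for i in range(W.shape[1]) if module_membership(W[:, i]).sum() > 1]
    out = dict(similarity_jaccard=[], similarity_cosine=[], spatial_spread=[],
               flagged_empty=n_shuffles == 0)
    if n_shuffles == 0:
        return out
    pos = np.asarray(roi_positions, dtype=float)
    for _ in range(n_shuffles):
        Wsh = np.stack([rng.permutation(W[:, i]) for i in multi], axis=1)
        for a in range(len(multi)):
            for b in range(a + 1, len(multi)):
                sim = module_similarity(Wsh[:, a], Wsh[:, b])
                out["similarity_jaccard"].append(sim["jaccard"])
                out["similarity_cosine"].append(sim["cosine"])
        perm = rng.permutation(len(pos))
        for i in multi:
            out["spatial_spread"].append(spatial_spread(W[:, i], pos[perm]))
    for key in ("similarity_jaccard", "similarity_cosine", "spatial_spread"):
        out[key] = np.asarray(out[key])
    return out
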