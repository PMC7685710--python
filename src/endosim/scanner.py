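"""Render synthetic imaging t-series by scanning a tilted excitation
ellipsoid along the probe's curved focal shell(s), with the three-regime
calibrated pixel-noise model.

Pixel regimes (radial distance measured on the nominal pixel grid):
  (i)   edge pixels (beyond the FOV support) carry detector dark noise;
  (ii)  interior pixels whose excitation volume contains no neuron voxel
        carry background noise;
  (iii) pixels sampling neurons average neuron fluorescence and per-voxel
        noise over every voxel inside the excitation ellipsoid(s).

The excitation ellipsoid is always orthogonal to the local focal shell, so
for aberrated probes it tilts increasingly toward the FOV edge; pixel
positions are mapped through the magnification model, giving a non-uniform
µm/px calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, sparse, stats
from scipy.spatial import cKDTree

from ._kernels import count_hits_per_pixel
from .optics import ImagingModel, intensity_mask_value, radial_calibration
from .scene import ActivitySet, NeuronVolume

__all__ = ["NoiseModel", "TSeries", "sample_pixel_noise", "render_tseries"]

SD_FLOOR = 1.0  # counts; the printed linear sd fits go negative at small means


@dataclass(frozen=True)
class NoiseModel:
    """Calibrated pixel-noise model (photon-count units).

    * dark: pixel mean from a two-component Gaussian mixture, per-frame sd
      linear in the mean;
    * background: pixel mean lognormal, sd linear in sqrt(mean);
    * roi: zero-mean voxel noise, sd linear in sqrt(voxel mean).
    """

    dark_weights: tuple[float, float] = (0.37, 0.63)
    dark_means: tuple[float, float] = (137.48, 126.83)
    dark_sds: tuple[float, float] = (48.96, 5.02)
    dark_sd_fit: tuple[float, float] = (-175.39, 1.57)  # sd = p1*mean + p0
    bg_logmean: float = 5.43
    bg_logsd: float = 0.36
    bg_sd_fit: tuple[float, float] = (-162.55, 18.28)  # sd = p1*sqrt(mean) + p0
    roi_sd_fit: tuple[float, float] = (-132.44, 16.94)  # sd = p1*sqrt(mean) + p0
    sd_floor: float = SD_FLOOR

    def dark_sd(self, mean):
        p0, p1 = self.dark_sd_fit
        return np.maximum(p1 * np.asarray(mean, dtype=float) + p0, self.sd_floor)

    def bg_sd(self, mean):
        p0, p1 = self.bg_sd_fit
        return np.maximum(p1 * np.sqrt(np.maximum(mean, 0.0)) + p0, self.sd_floor)

    def roi_sd(self, mean):
        p0, p1 = self.roi_sd_fit
        return np.maximum(p1 * np.sqrt(np.maximum(mean, 0.0)) + p0, self.sd_floor)

    def bg_mean_moments(self) -> tuple[float, float, float]:
        """(E[mu], Var[mu], E[sd(mu)^2]) under the lognormal pixel-mean law."""
        return _bg_moments(self.bg_logmean, self.bg_logsd, self.bg_sd_fit, self.sd_floor)


@lru_cache(maxsize=8)
def _bg_moments(logmean, logsd, sd_fit, floor):
    e_mu = float(np.exp(logmean + logsd**2 / 2))
    var_mu = float((np.exp(logsd**2) - 1) * np.exp(2 * logmean + logsd**2))
    pdf = stats.lognorm(s=logsd, scale=np.exp(logmean)).pdf
    p0, p1 = sd_fit
    f = lambda x: max(p1 * np.sqrt(x) + p0, floor) ** 2 * pdf(x)
    e_sd2, _ = integrate.quad(f, 0, np.exp(logmean + 8 * logsd), limit=200)
    return e_mu, var_mu, float(e_sd2)


def sample_pixel_noise(
    noise_model: NoiseModel,
    regime: str,
    n_frames: int,
    mean_for_roi: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """A single pixel's noise trace under one of the three regimes."""
    rng = np.random.default_rng() if rng is None else rng
    nm = noise_model
    if regime == "dark":
        comp = rng.random() < nm.dark_weights[0]
        i = 0 if comp else 1
        mu = rng.normal(nm.dark_means[i], nm.dark_sds[i])
        return mu + nm.dark_sd(mu) * rng.standard_normal(n_frames)
    if regime == "background":
        mu = rng.lognormal(nm.bg_logmean, nm.bg_logsd)
        return mu + nm.bg_sd(mu) * rng.standard_normal(n_frames)
    if regime == "roi":
        if mean_for_roi is None:
            raise ValueError("roi regime requires mean_for_roi")
        return nm.roi_sd(mean_for_roi) * rng.standard_normal(n_frames)
    raise ValueError(f"unknown noise regime: {regime!r}")


@dataclass
class TSeries:
    """A rendered frame stack plus per-pixel ground-truth provenance."""

    frames: np.ndarray  # (n_frames, H, W) float32
    frame_rate: float
    pixel_size_um: float  # nominal, at the FOV center
    pixel_pos_um: np.ndarray  # (H, W, 2) calibrated positions, FOV-centered
    edge_mask: np.ndarray  # (H, W) bool, True where dark regime applies
    # provenance: parallel arrays over (pixel, neuron) contributions
    contrib_pixel: np.ndarray  # flat pixel index (row-major)
    contrib_neuron: np.ndarray  # neuron id
    contrib_voxels: np.ndarray  # voxels of the neuron inside the ellipsoid(s)
    probe: str = ""

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def provenance_at(self, row: int, col: int) -> list[int]:
        """Ids of neurons contributing signal to pixel (row, col)."""
        flat = row * self.frames.shape[2] + col
        return sorted(self.contrib_neuron[self.contrib_pixel == flat].tolist())

    def footprints(self) -> dict[int, np.ndarray]:
        """neuron id -> flat pixel indices collecting signal from it."""
        out: dict[int, np.ndarray] = {}
        order = np.argsort(self.contrib_neuron, kind="stable")
        nid = self.contrib_neuron[order]
        pix = self.contrib_pixel[order]
        for i in np.unique(nid):
            out[int(i)] = pix[nid == i]
        return out

    def radial_distance_um(self) -> np.ndarray:
        """(H, W) calibrated radial distance from the FOV center."""
        return np.hypot(self.pixel_pos_um[..., 0], self.pixel_pos_um[..., 1])


def _sym_qform(normal: np.ndarray, a: float, b: float) -> np.ndarray:
    """Quadratic form (xx, yy, zz, xy, xz, yz) of an ellipsoid of revolution
    with lateral semi-axis ``a`` and axial semi-axis ``b`` along ``normal``."""
    n = normal / np.linalg.norm(normal)
    ia2, ib2 = 1.0 / a**2, 1.0 / b**2
    M = ia2 * np.eye(3) + (ib2 - ia2) * np.outer(n, n)
    return np.array([M[0, 0], M[1, 1], M[2, 2], M[0, 1], M[0, 2], M[1, 2]])


def _bbox_half_extents(normal: np.ndarray, a: float, b: float) -> np.ndarray:
    """Axis-aligned bounding-box half extents of the same ellipsoid."""
    n = normal / np.linalg.norm(normal)
    C = a**2 * np.eye(3) + (b**2 - a**2) * np.outer(n, n)
    return np.sqrt(np.diag(C))


def render_tseries(
    volume: NeuronVolume,
    activity: ActivitySet,
    imaging_model: ImagingModel,
    noise_model: NoiseModel | None = None,
    n_frames: int | None = None,
    rng: np.random.Generator | None = None,
    fov_size_um: float = 500.0,
    pixel_size_um: float = 2.5,
    edge_radius_um: float = 250.0,
) -> TSeries:
    """Scan the excitation ellipsoid(s) over the focal shell(s) and render.

    The volume is voxelized at ``volume.voxel_size``; every voxel inside the
    excitation volume(s) of a pixel contributes (neuron fluorescence plus
    roi-regime noise for neuron-shell voxels, background noise otherwise) and
    the pixel value is the average over those voxels, modulated by the radial
    intensity mask. Pixel centers are placed at calibrated (magnification-
    corrected) positions. Nuclei contribute no signal.
    """
    noise_model = NoiseModel() if noise_model is None else noise_model
    rng = np.random.default_rng() if rng is None else rng
    n_frames = activity.n_frames if n_frames is None else int(n_frames)
    if n_frames > activity.n_frames:
        raise ValueError("activity does not cover n_frames")
    if volume.n_neurons != activity.n_neurons:
        raise ValueError("volume and activity sizes do not match")

    npx = int(round(fov_size_um / pixel_size_um))
    H = W = npx
    # nominal FOV-centered pixel coordinates
    coord = (np.arange(npx) + 0.5) * pixel_size_um - fov_size_um / 2.0
    gx, gy = np.meshgrid(coord, coord, indexing="xy")
    rho = np.hypot(gx, gy)  # nominal radius
    edge_mask = rho > edge_radius_um

    # calibrated radial mapping (non-uniform µm/px)
    r_true = radial_calibration(imaging_model.magnification, rho.ravel()).reshape(rho.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(rho > 0, r_true / rho, 1.0)
    pos = np.stack([gx * scale, gy * scale], axis=-1)  # (H, W, 2) true µm

    interior = ~edge_mask
    pidx = np.flatnonzero(interior.ravel())  # flat indices of interior pixels
    pr = r_true.ravel()[pidx]
    px = pos[..., 0].ravel()[pidx]
    py = pos[..., 1].ravel()[pidx]

    # volume coordinates: FOV center maps to the volume's (x, y) center
    cx, cy = volume.extent[0] / 2.0, volume.extent[1] / 2.0
    z_ext = volume.extent[2]
    psf = imaging_model.psf
    sc = imaging_model.ellipsoid_scale
    n_lobes = len(imaging_model.surfaces)
    n_int = len(pidx)

    centers = np.zeros((n_int, n_lobes, 3))
    Ms = np.zeros((n_int, n_lobes, 6))
    ext_xy = np.zeros((n_int, n_lobes))
    ext_z = np.zeros((n_int, n_lobes))
    lobe_ok = np.zeros((n_int, n_lobes), dtype=np.bool_)

    rq = np.clip(pr, 0.0, psf.support_radius)
    lat = sc * psf.lateral_fwhm(rq)
    ax = sc * psf.axial_fwhm(rq)
    for l, surf in enumerate(imaging_model.surfaces):
        R = surf.curvature_radius
        rr = np.minimum(pr, R - 1e-9)
        zs = surf.apex_z + surf.sign * (R - np.sqrt(R**2 - rr**2))
        sin_t = np.clip(rr / R, 0.0, 1.0)
        cos_t = np.sqrt(1.0 - sin_t**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(pr > 0, px / pr, 0.0)
            uy = np.where(pr > 0, py / pr, 0.0)
        for i in range(n_int):
            nvec = np.array([sin_t[i] * ux[i], sin_t[i] * uy[i], cos_t[i]])
            if nvec[2] <= 0:
                nvec = np.array([0.0, 0.0, 1.0])
            c = np.array([cx + px[i], cy + py[i], zs[i]])
            centers[i, l] = c
            Ms[i, l] = _sym_qform(nvec, lat[i], ax[i])
            he = _bbox_half_extents(nvec, lat[i], ax[i])
            ext_xy[i, l] = max(he[0], he[1])
            ext_z[i, l] = he[2]
            lobe_ok[i, l] = (zs[i] - he[2] <= z_ext) and (zs[i] + he[2] >= 0.0)

    # total voxel count inside the union of lobes, one representative pixel
    # per 1-px radial ring (shape and tilt depend on radius only)
    vs = np.asarray(volume.voxel_size)
    ring = np.round(rho.ravel()[pidx] / pixel_size_um).astype(int)
    n_tot = np.zeros(n_int, dtype=np.int64)
    for rv in np.unique(ring):
        members = np.flatnonzero(ring == rv)
        rep = members[0]
        zlists = []
        for l in range(n_lobes):
            if not lobe_ok[rep, l]:
                continue
            z0, z1 = centers[rep, l, 2] - ext_z[rep, l], centers[rep, l, 2] + ext_z[rep, l]
            k0 = max(int(np.floor(z0 / vs[2])), 0)
            k1 = min(int(np.ceil(z1 / vs[2])), int(round(z_ext / vs[2])) - 1)
            if k1 >= k0:
                zlists.append(np.arange(k0, k1 + 1))
        if not zlists:
            continue
        zk = np.unique(np.concatenate(zlists))
        exy = ext_xy[rep].max()
        x0 = np.floor((centers[rep, 0, 0] - exy) / vs[0])
        x1 = np.ceil((centers[rep, 0, 0] + exy) / vs[0])
        y0 = np.floor((centers[rep, 0, 1] - exy) / vs[1])
        y1 = np.ceil((centers[rep, 0, 1] + exy) / vs[1])
        xs = (np.arange(x0, x1 + 1) + 0.5) * vs[0]
        ys = (np.arange(y0, y1 + 1) + 0.5) * vs[1]
        zs_ = (zk + 0.5) * vs[2]
        gxx, gyy, gzz = np.meshgrid(xs, ys, zs_, indexing="ij")
        grid = np.column_stack([gxx.ravel(), gyy.ravel(), gzz.ravel()])
        cnt = count_hits_per_pixel(grid, centers[rep:rep + 1], Ms[rep:rep + 1],
                                   lobe_ok[rep:rep + 1])
        n_tot[members] = cnt[0]

    # neuron-shell voxel counts per (pixel, neuron) pair
    tree = cKDTree(np.column_stack([cx + px, cy + py]))
    reach = ext_xy.max(axis=1)
    contrib_pix: list[np.ndarray] = []
    contrib_nid: list[np.ndarray] = []
    contrib_k: list[np.ndarray] = []
    max_reach = float(reach.max()) if n_int else 0.0
    for neuron in volume.neurons:
        cand = np.asarray(tree.query_ball_point(neuron.center[:2],
                                                max_reach + neuron.radius))
        if cand.size == 0:
            continue
        keep = np.hypot(cx + px[cand] - neuron.center[0],
                        cy + py[cand] - neuron.center[1]) <= reach[cand] + neuron.radius
        cand = cand[keep]
        if cand.size == 0:
            continue
        zok = np.zeros(len(cand), dtype=bool)
        for l in range(n_lobes):
            zok |= lobe_ok[cand, l] & (
                np.abs(centers[cand, l, 2] - neuron.center[2])
                <= ext_z[cand, l] + neuron.radius)
        cand = cand[zok]
        if cand.size == 0:
            continue
        vox = volume.shell_voxels(neuron)
        if vox.size == 0:
            continue
        counts = count_hits_per_pixel(vox, centers[cand], Ms[cand], lobe_ok[cand])
        hit = counts > 0
        if np.any(hit):
            contrib_pix.append(pidx[cand[hit]])
            contrib_nid.append(np.full(int(hit.sum()), neuron.id, dtype=np.int64))
            contrib_k.append(counts[hit])

    if contrib_pix:
        c_pix = np.concatenate(contrib_pix)
        c_nid = np.concatenate(contrib_nid)
        c_k = np.concatenate(contrib_k)
    else:
        c_pix = np.zeros(0, dtype=np.int64)
        c_nid = np.zeros(0, dtype=np.int64)
        c_k = np.zeros(0, dtype=np.int64)

    # --- assemble frames ---------------------------------------------------
    frames = np.empty((n_frames, H * W), dtype=np.float32)
    nm = noise_model

    # regime (i): edge pixels, dark noise
    eidx = np.flatnonzero(edge_mask.ravel())
    comp = rng.random(len(eidx)) < nm.dark_weights[0]
    mu_d = np.where(comp,
                    rng.normal(nm.dark_means[0], nm.dark_sds[0], len(eidx)),
                    rng.normal(nm.dark_means[1], nm.dark_sds[1], len(eidx)))
    frames[:, eidx] = (mu_d + nm.dark_sd(mu_d) * rng.standard_normal((n_frames, len(eidx)))).astype(np.float32)

    # The intensity mask is an excitation-efficiency profile: it scales every
    # light-derived mean BEFORE noise generation (detector dark noise is not
    # scaled), and the noise sd follows the printed fits evaluated at the
    # masked mean — dimming a region therefore costs signal-to-noise.
    mask_val = intensity_mask_value(imaging_model.mask, pr)

    # regime (ii): interior pixels with no neuron in the excitation volume
    flat_to_int = np.full(H * W, -1, dtype=np.int64)
    flat_to_int[pidx] = np.arange(n_int)
    has_neuron = np.zeros(n_int, dtype=bool)
    has_neuron[flat_to_int[c_pix]] = True
    bg_int = np.flatnonzero(~has_neuron)
    mu_b = rng.lognormal(nm.bg_logmean, nm.bg_logsd, len(bg_int)) * mask_val[bg_int]
    tr = mu_b + nm.bg_sd(mu_b) * rng.standard_normal((n_frames, len(bg_int)))
    frames[:, pidx[bg_int]] = tr.astype(np.float32)

    # regime (iii): voxel-averaged neuron signal + pixel-level noise.
    # The mean pixel value averages neuron fluorescence and background-voxel
    # means over the excitation volume(s); the noise is drawn once per pixel
    # and frame with sd from the ROI-pixel fit at the pixel's mean intensity
    # (the fit was calibrated on pixel traces, so applying it per voxel and
    # averaging would under-disperse the rendered pixels by sqrt(n_voxels)).
    roi_int = np.flatnonzero(has_neuron)
    if len(roi_int):
        fl = activity.fluorescence[:, :n_frames]
        mean_f = fl.mean(axis=1)
        rows = flat_to_int[c_pix]
        row_map = np.full(n_int, -1, dtype=np.int64)
        row_map[roi_int] = np.arange(len(roi_int))
        K = sparse.csr_matrix(
            (c_k.astype(float), (row_map[rows], c_nid)),
            shape=(len(roi_int), volume.n_neurons),
        )
        signal = K @ fl  # (n_roi_px, n_frames)
        k_sum = np.asarray(K.sum(axis=1)).ravel()
        ntot_roi = np.maximum(n_tot[roi_int], k_sum).astype(float)
        n_bg = np.maximum(ntot_roi - k_sum, 0.0)
        e_mu, var_mu, _ = nm.bg_mean_moments()
        s_const = n_bg * e_mu + np.sqrt(n_bg * var_mu) * rng.standard_normal(len(roi_int))
        m = mask_val[roi_int]
        mean_pix = m * (np.asarray(K @ mean_f).ravel() + s_const) / ntot_roi
        sd_pix = nm.roi_sd(mean_pix)
        vals = m * (signal.T + s_const) / ntot_roi
        vals += sd_pix * rng.standard_normal((n_frames, len(roi_int)))
        frames[:, pidx[roi_int]] = vals.astype(np.float32)

    frames = np.maximum(frames, 0.0).reshape(n_frames, H, W)
    return TSeries(
        frames=frames,
        frame_rate=activity.frame_rate,
        pixel_size_um=pixel_size_um,
        pixel_pos_um=pos,
        edge_mask=edge_mask,
        contrib_pixel=c_pix,
        contrib_neuron=c_nid,
        contrib_voxels=c_k,
        probe=imaging_model.name,
    )
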