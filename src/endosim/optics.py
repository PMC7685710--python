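"""Probe optics: focal-surface geometry, radially varying PSF, magnification
distortion, intensity mask, and the bead-stack characterization fits.

A gradient-index (GRIN) relay suffers strong field curvature and spherical
aberration off-axis: the focal "plane" is a curved shell and the excitation
point-spread function (PSF) broadens — and for uncorrected probes splits into
two lobes — with radial distance. A microfabricated aspheric corrector
flattens the response. The forward model represents each probe type as a
bundle of spherical focal shells, quartic FWHM-vs-radius curves, a quadratic
magnification fit, and a radial intensity mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

__all__ = [
    "AsphereProfile",
    "asphere_sag",
    "ImagingSurface",
    "surface_z",
    "PSFModel",
    "psf_at_radius",
    "MagnificationModel",
    "magnification_factor",
    "radial_calibration",
    "IntensityMask",
    "intensity_mask_value",
    "ImagingModel",
    "corrected_model",
    "uncorrected_model",
    "characterize_psf_stack",
    "effective_fov_radius",
]


# ---------------------------------------------------------------------------
# aspheric lens profile

@dataclass(frozen=True)
class AsphereProfile:
    """Even aspheric surface: curvature ``c`` (1/µm), conic ``k``, and
    polynomial coefficients alpha_n multiplying r^(2n), n = 1..len(alpha)."""

    c: float
    k: float = 0.0
    alpha: tuple[float, ...] = ()


def asphere_sag(profile: AsphereProfile, r) -> np.ndarray:
    """Sag Z(r) = c r^2 / (1 + sqrt(1 - (1+k) c^2 r^2)) + sum_n alpha_n r^(2n)."""
    r = np.asarray(r, dtype=float)
    disc = 1.0 - (1.0 + profile.k) * profile.c**2 * r**2
    if np.any(disc < 0):
        raise ValueError("asphere sag undefined: 1-(1+k)c^2 r^2 < 0")
    z = profile.c * r**2 / (1.0 + np.sqrt(disc))
    for n, a in enumerate(profile.alpha, start=1):
        z = z + a * r ** (2 * n)
    return z


# ---------------------------------------------------------------------------
# focal shells

@dataclass(frozen=True)
class ImagingSurface:
    """Spherical focal shell: z(r) = apex_z + sign * (R - sqrt(R^2 - r^2))."""

    curvature_radius: float  # µm; np.inf = flat
    apex_z: float = 0.0
    sign: float = 1.0  # +1: curves toward larger z (into the tissue)

    def __post_init__(self):
        if self.curvature_radius <= 0:
            raise ValueError("curvature_radius must be positive")


def surface_z(surface: ImagingSurface, x, y) -> np.ndarray:
    """Axial position of the shell above (x, y); domain |r| <= R."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r2 = x**2 + y**2
    R = surface.curvature_radius
    if np.isinf(R):
        return np.broadcast_to(np.asarray(surface.apex_z, dtype=float), r2.shape).copy()
    if np.any(r2 > R**2):
        raise ValueError("point outside shell support")
    return surface.apex_z + surface.sign * (R - np.sqrt(R**2 - r2))


def surface_tilt(surface: ImagingSurface, dist_r) -> np.ndarray:
    """Angle (rad) between the local surface normal and the optical axis."""
    r = np.asarray(dist_r, dtype=float)
    R = surface.curvature_radius
    if np.isinf(R):
        return np.zeros_like(r)
    return np.arcsin(np.clip(r / R, -1.0, 1.0))


# ---------------------------------------------------------------------------
# PSF model

def _quartic(r, c0, c2, c4):
    return c0 + c2 * r**2 + c4 * r**4


@dataclass(frozen=True)
class PSFModel:
    """Radially varying excitation ellipsoid via symmetric quartic FWHM curves.

    ``lateral``/``axial`` hold (c0, c2, c4) of FWHM(r) = c0 + c2 r^2 + c4 r^4
    in µm; only even powers appear, respecting the cylindrical symmetry of
    the optical system.
    """

    lateral: tuple[float, float, float]
    axial: tuple[float, float, float]
    support_radius: float = 250.0  # µm

    def lateral_fwhm(self, dist_r) -> np.ndarray:
        return _quartic(np.asarray(dist_r, dtype=float), *self.lateral)

    def axial_fwhm(self, dist_r) -> np.ndarray:
        return _quartic(np.asarray(dist_r, dtype=float), *self.axial)


def psf_at_radius(psf_model: PSFModel, dist_r: float) -> tuple[float, float]:
    """(lateral, axial) FWHM in µm at radial distance ``dist_r``.

    The excitation ellipsoid at that position has its axial axis orthogonal
    to the local focal shell; the caller applies the orientation.
    """
    if dist_r < 0 or dist_r > psf_model.support_radius:
        raise ValueError("dist_r outside PSF model support")
    lat = float(psf_model.lateral_fwhm(dist_r))
    ax = float(psf_model.axial_fwhm(dist_r))
    if lat <= 0 or ax <= 0:
        raise ValueError("PSF FWHM must be positive inside the FOV")
    return lat, ax


def effective_fov_radius(psf_model: PSFModel, threshold: float = 10.0,
                         tol: float = 0.1) -> float:
    """First radius where the fitted axial FWHM curve up-crosses ``threshold``.

    Returns the support radius if the curve never crosses (homogeneous probe).
    Bisection to ``tol`` µm.
    """
    rmax = psf_model.support_radius
    f = lambda r: float(psf_model.axial_fwhm(r)) - threshold
    grid = np.linspace(0.0, rmax, 1001)
    vals = psf_model.axial_fwhm(grid) - threshold
    idx = np.nonzero((vals[:-1] <= 0) & (vals[1:] > 0))[0]
    if len(idx) == 0:
        return rmax
    return float(brentq(f, grid[idx[0]], grid[idx[0] + 1], xtol=tol))


# ---------------------------------------------------------------------------
# magnification

@dataclass(frozen=True)
class MagnificationModel:
    """Quadratic magnification-vs-radius fit: M(r) = p0 + p1 r + p2 r^2."""

    p0: float
    p1: float
    p2: float


def magnification_factor(model: MagnificationModel, dist_r) -> np.ndarray:
    """Magnification at radial distance ``dist_r`` (µm)."""
    r = np.asarray(dist_r, dtype=float)
    if np.any(r < 0):
        raise ValueError("dist_r must be non-negative")
    return model.p0 + model.p1 * r + model.p2 * r**2


def radial_calibration(
    model: MagnificationModel,
    nominal_radius_um: np.ndarray,
    step_um: float = 0.25,
) -> np.ndarray:
    """Map nominal (uniform-pixel) radius to calibrated true radius in µm.

    The relative distortion D(r) = M(r)/M(0) gives the local pixel density;
    the true radius solves dr/dρ = 1/D(r) with r(0) = 0, integrated by small
    fixed steps, so the nominal pixel pitch holds at the FOV center.
    """
    rho = np.atleast_1d(np.asarray(nominal_radius_um, dtype=float))
    rho_max = float(rho.max()) if rho.size else 0.0
    grid = np.arange(0.0, rho_max + step_um, step_um)
    r_true = np.empty_like(grid)
    r_true[0] = 0.0
    m0 = magnification_factor(model, 0.0)
    for i in range(1, len(grid)):
        D = magnification_factor(model, r_true[i - 1]) / m0
        r_true[i] = r_true[i - 1] + step_um / max(float(D), 1e-9)
    out = np.interp(rho, grid, r_true)
    return out if np.asarray(nominal_radius_um).ndim else float(out[0])


# ---------------------------------------------------------------------------
# intensity mask

@dataclass(frozen=True)
class IntensityMask:
    """Radial excitation-efficiency multiplier, normalized to 1 on-axis.

    Parametric Gaussian fall-off by default; a tabulated (radius, value)
    profile measured from a subresolved fluorescent layer may be supplied
    instead and is linearly interpolated.
    """

    sigma_um: float = np.inf
    table: tuple[tuple[float, ...], tuple[float, ...]] | None = None


def intensity_mask_value(mask: IntensityMask, dist_r) -> np.ndarray:
    r = np.asarray(dist_r, dtype=float)
    if mask.table is not None:
        radii, vals = (np.asarray(a, dtype=float) for a in mask.table)
        v = np.interp(r, radii, vals)
        v0 = np.interp(0.0, radii, vals)
        out = v / v0 if v0 > 0 else v
    elif np.isinf(mask.sigma_um):
        out = np.ones_like(r)
    else:
        out = np.exp(-0.5 * (r / mask.sigma_um) ** 2)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# per-probe bundles

@dataclass(frozen=True)
class ImagingModel:
    """Everything the scanner needs to know about one probe type."""

    name: str
    surfaces: tuple[ImagingSurface, ...]
    psf: PSFModel
    magnification: MagnificationModel
    mask: IntensityMask = field(default_factory=IntensityMask)
    ellipsoid_scale: float = 1.0  # half-axes = scale * FWHM


def corrected_model(apex_z: float = 0.0) -> ImagingModel:
    """Aberration-corrected probe: one focal shell (R = 400 µm) and a
    radially homogeneous PSF (lateral 1 µm, axial 8 µm FWHM)."""
    return ImagingModel(
        name="corrected",
        surfaces=(ImagingSurface(curvature_radius=400.0, apex_z=apex_z),),
        psf=PSFModel(lateral=(1.0, 0.0, 0.0), axial=(8.0, 0.0, 0.0)),
        magnification=MagnificationModel(0.76, -6.24e-4, 1.95e-5),
        mask=IntensityMask(sigma_um=400.0),
    )


def uncorrected_model(apex_z: float = 0.0) -> ImagingModel:
    """Aberrated probe: two focal shells (R = 265 and 2000 µm) and a PSF that
    broadens with radius (lateral 1 -> 2 µm, axial 8 -> 40 µm at 250 µm,
    symmetric quartics with equal weight on the r^2 and r^4 terms)."""
    r0 = 250.0
    lat = (1.0, 0.5 / r0**2, 0.5 / r0**4)
    ax = (8.0, 16.0 / r0**2, 16.0 / r0**4)
    return ImagingModel(
        name="uncorrected",
        surfaces=(
            ImagingSurface(curvature_radius=265.0, apex_z=apex_z),
            ImagingSurface(curvature_radius=2000.0, apex_z=apex_z),
        ),
        psf=PSFModel(lateral=lat, axial=ax),
        magnification=MagnificationModel(0.73, -2.91e-4, 8.11e-6),
        mask=IntensityMask(sigma_um=200.0),
    )


def probe_model(name: str) -> ImagingModel:
    if name == "corrected":
        return corrected_model()
    if name == "uncorrected":
        return uncorrected_model()
    raise ValueError(f"unknown probe type: {name!r}")


# ---------------------------------------------------------------------------
# PSF characterization from bead stacks

def _gauss(x, a, mu, sd, b):
    return a * np.exp(-0.5 * ((x - mu) / sd) ** 2) + b


def _gauss2(x, a1, mu1, sd1, a2, mu2, sd2, b):
    return (a1 * np.exp(-0.5 * ((x - mu1) / sd1) ** 2)
            + a2 * np.exp(-0.5 * ((x - mu2) / sd2) ** 2) + b)


_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _fit_profile(coord: np.ndarray, profile: np.ndarray,
                 allow_double: bool) -> tuple[float, bool]:
    """FWHM of a 1D bead profile; optionally choose a two-Gaussian model.

    The double-Gaussian model is preferred when it cuts the residual sum of
    squares by more than 20% and its peaks are separated by more than one
    single-Gaussian FWHM; the axial resolution is then the peak separation.
    """
    b0 = float(profile.min())
    a0 = float(profile.max() - b0)
    mu0 = float(coord[np.argmax(profile)])
    sd0 = max((coord[-1] - coord[0]) / 10.0, 1e-3)
    p1, _ = curve_fit(_gauss, coord, profile, p0=(a0, mu0, sd0, b0), maxfev=20000)
    fwhm1 = abs(p1[2]) * _FWHM
    rss1 = float(np.sum((profile - _gauss(coord, *p1)) ** 2))
    if not allow_double:
        return fwhm1, False
    from scipy.signal import find_peaks

    inits = [(a0, mu0 - fwhm1, sd0, a0, mu0 + fwhm1, sd0, b0)]
    pk, props = find_peaks(profile, prominence=0.1 * a0)
    if len(pk) >= 2:
        top = pk[np.argsort(props["prominences"])[-2:]]
        sd_init = max(abs(p1[2]) / 2.0, 1e-3)
        inits.insert(0, (profile[top[0]] - b0, coord[top[0]], sd_init,
                         profile[top[1]] - b0, coord[top[1]], sd_init, b0))
    best = None
    for p0_ in inits:
        try:
            p2, _ = curve_fit(_gauss2, coord, profile, p0=p0_, maxfev=20000)
        except RuntimeError:
            continue
        rss2 = float(np.sum((profile - _gauss2(coord, *p2)) ** 2))
        if best is None or rss2 < best[0]:
            best = (rss2, p2)
    if best is not None:
        rss2, p2 = best
        sep = abs(p2[4] - p2[1])
        lobe_fwhm = 0.5 * (abs(p2[2]) + abs(p2[5])) * _FWHM
        # prefer two lobes only when they clearly fit better and are resolved
        # (separation beyond their own width)
        if rss2 < 0.8 * rss1 and sep > lobe_fwhm:
            return sep, True
    return fwhm1, False


def _mad_screen(values: np.ndarray, n_mad: float = 3.5) -> np.ndarray:
    """Median-absolute-deviation outlier mask (True = keep)."""
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        return np.ones_like(values, dtype=bool)
    return np.abs(values - med) <= n_mad * mad / 0.6745


def characterize_psf_stack(
    bead_z_stacks: list[np.ndarray],
    radial_positions: np.ndarray,
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5),
    axial_threshold_um: float = 10.0,
) -> dict:
    """Measure lateral/axial resolution vs radius from isolated-bead z-stacks.

    For each stack (z, y, x), the x/y/z intensity profiles through the peak
    voxel are fitted with Gaussians; lateral resolution is the mean of the x
    and y FWHM and axial resolution the z FWHM — or the two-peak separation
    when a double Gaussian clearly fits the z profile better (aberrated
    probes develop a double-lobed axial response off-axis). Replicate groups
    at the same radius are screened for outliers at 3.5 MAD. Resolution vs
    radius is fitted with symmetric quartics, and the effective-FOV radius is
    where the fitted axial curve crosses ``axial_threshold_um``.

    Returns a dict with keys ``table`` (per-stack records), ``lateral_fit``,
    ``axial_fit`` (c0, c2, c4), ``psf_model`` and ``effective_fov_radius``.
    """
    dz, dy, dx = voxel_size[2], voxel_size[1], voxel_size[0]
    radial_positions = np.asarray(radial_positions, dtype=float)
    records = []
    for r, stack in zip(radial_positions, bead_z_stacks):
        stack = np.asarray(stack, dtype=float)
        try:
            kz, ky, kx = np.unravel_index(np.argmax(stack), stack.shape)
            zc = (np.arange(stack.shape[0]) - kz) * dz
            yc = (np.arange(stack.shape[1]) - ky) * dy
            xc = (np.arange(stack.shape[2]) - kx) * dx
            fx, _ = _fit_profile(xc, stack[kz, ky, :], allow_double=False)
            fy, _ = _fit_profile(yc, stack[kz, :, kx], allow_double=False)
            fz, double = _fit_profile(zc, stack[:, ky, kx], allow_double=True)
        except RuntimeError:
            warnings.warn(f"bead fit failed at r={r}; record excluded", stacklevel=2)
            continue
        records.append(dict(dist_r_um=float(r), fwhm_x_um=fx, fwhm_y_um=fy,
                            fwhm_lat_um=0.5 * (fx + fy), fwhm_ax_um=fz,
                            double_lobed=double))
    if not records:
        raise ValueError("no bead stack could be fitted")

    r_arr = np.array([rec["dist_r_um"] for rec in records])
    lat = np.array([rec["fwhm_lat_um"] for rec in records])
    ax = np.array([rec["fwhm_ax_um"] for rec in records])
    keep = np.ones(len(records), dtype=bool)
    for rv in np.unique(r_arr):
        grp = r_arr == rv
        if grp.sum() >= 4:
            keep[grp] &= _mad_screen(ax[grp]) & _mad_screen(lat[grp])

    def fit_quartic(y):
        A = np.column_stack([np.ones_like(r_arr[keep]), r_arr[keep] ** 2, r_arr[keep] ** 4])
        coef, *_ = np.linalg.lstsq(A, y[keep], rcond=None)
        return tuple(float(c) for c in coef)

    lat_fit = fit_quartic(lat)
    ax_fit = fit_quartic(ax)
    model = PSFModel(lateral=lat_fit, axial=ax_fit,
                     support_radius=float(max(r_arr.max(), 1.0)))
    return dict(
        table=records,
        kept=keep,
        lateral_fit=lat_fit,
        axial_fit=ax_fit,
        psf_model=model,
        effective_fov_radius=effective_fov_radius(model, axial_threshold_um),
    )
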