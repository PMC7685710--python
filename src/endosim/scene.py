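"""Ground-truth scene generation: neuron geometry and spiking/calcium/fluorescence activity.

Neurons are non-overlapping spheres with a non-fluorescent nucleus, placed
uniformly at random in a tissue volume until a target density is reached.
Spiking is a sum of a private Poisson process and a shared ("common input")
Poisson source; calcium follows an AR(1) model and fluorescence a Hill
saturation of calcium with additive Gaussian noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Neuron",
    "NeuronVolume",
    "SynchronicityMatrix",
    "ActivitySet",
    "place_neurons",
    "build_synchronicity",
    "simulate_spikes",
    "spikes_to_calcium",
    "calcium_to_fluorescence",
    "simulate_activity",
    "simulate_state_session",
]

#: Default geometry/activity parameters (units: µm, spikes/frame, frames).
RADIUS_MEAN_UM = 7.95
RADIUS_SD_UM = 1.31
SHELL_MEAN_UM = 4.0
SHELL_SD_UM = 1.0
DENSITY_PER_MM3 = 83_100.0
RHO_DEFAULT = 0.4
GAMMA_DEFAULT = 0.7
COMMON_INPUT_PROB = 0.8
#: Fraction of each neuron's rate carried by the shared common source,
#: calibrated so that linked-pair calcium correlation p*q reproduces the
#: target mean pairwise correlation 0.084 at p = 0.8.
COMMON_FRACTION_DEFAULT = 0.105

HILL_PARAMS = dict(baseline=0.0, amplitude=1500.0, hill_n=1.0, kd=1.0, noise_var=0.05)


@dataclass(frozen=True)
class Neuron:
    """A spherical neuron with a non-fluorescent nuclear core.

    The fluorescent region is the spherical shell between radius
    ``radius - shell_width`` and ``radius``.
    """

    id: int
    center: np.ndarray  # (3,) µm
    radius: float  # µm
    shell_width: float  # µm

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (0 < self.shell_width <= self.radius):
            raise ValueError("shell_width must be in (0, radius]")

    @property
    def nucleus_radius(self) -> float:
        return self.radius - self.shell_width


@dataclass
class NeuronVolume:
    """A population of non-overlapping neurons inside a rectangular volume."""

    extent: tuple[float, float, float]  # (x, y, z) µm
    neurons: list[Neuron] = field(default_factory=list)
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 1.0)
    target_density: float = DENSITY_PER_MM3  # cells / mm^3

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def volume_mm3(self) -> float:
        return float(np.prod(self.extent)) * 1e-9

    @property
    def density(self) -> float:
        v = self.volume_mm3
        return self.n_neurons / v if v > 0 else 0.0

    def centers(self) -> np.ndarray:
        if not self.neurons:
            return np.zeros((0, 3))
        return np.stack([n.center for n in self.neurons])

    def radii(self) -> np.ndarray:
        return np.array([n.radius for n in self.neurons])

    def shell_voxels(self, neuron: Neuron) -> np.ndarray:
        """World-grid voxel centers inside the neuron's fluorescent shell.

        Voxel centers lie at ``(k + 0.5) * voxel_size`` on the volume grid.
        """
        vs = np.asarray(self.voxel_size)
        lo = np.floor((neuron.center - neuron.radius) / vs).astype(int)
        hi = np.ceil((neuron.center + neuron.radius) / vs).astype(int)
        ax = [(np.arange(lo[d], hi[d]) + 0.5) * vs[d] for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        d = np.linalg.norm(pts - neuron.center, axis=1)
        keep = (d <= neuron.radius) & (d >= neuron.nucleus_radius)
        return pts[keep]


@dataclass
class SynchronicityMatrix:
    """Binary symmetric link matrix: 1 marks a pair driven by common input."""

    matrix: np.ndarray
    common_input_probability: float

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("entries must be binary")


@dataclass
class ActivitySet:
    """Per-neuron spike counts, calcium, and fluorescence, frame-aligned."""

    frame_rate: float  # Hz
    spikes: np.ndarray  # (n_neurons, n_frames) nonnegative int
    calcium: np.ndarray  # (n_neurons, n_frames) nonnegative
    fluorescence: np.ndarray  # (n_neurons, n_frames)
    params: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.spikes.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[0]


def place_neurons(
    extent: tuple[float, float, float],
    target_density: float = DENSITY_PER_MM3,
    radius_mean: float = RADIUS_MEAN_UM,
    radius_sd: float = RADIUS_SD_UM,
    shell_mean: float = SHELL_MEAN_UM,
    shell_sd: float = SHELL_SD_UM,
    rng: np.random.Generator | None = None,
    max_attempts_factor: int = 50,
) -> NeuronVolume:
    """Rejection-sample non-overlapping spheres until the target density.

    Radii are drawn from a normal distribution truncated above 1 µm and shell
    widths from a normal truncated to (0, radius]. Placement is uniform inside
    the volume with every sphere fully contained; candidates overlapping an
    accepted sphere (center distance < sum of radii) are rejected. Gives up
    with a warning after ``max_attempts_factor`` times the target count.
    """
    extent = tuple(float(e) for e in extent)
    if any(e < 0 for e in extent):
        raise ValueError("extent must be non-negative")
    if target_density <= 0:
        raise ValueError("target_density must be positive")
    rng = np.random.default_rng() if rng is None else rng

    vol = NeuronVolume(extent=extent, target_density=target_density)
    volume_mm3 = float(np.prod(extent)) * 1e-9
    n_target = int(round(target_density * volume_mm3))
    if n_target == 0 or min(extent) <= 0:
        return vol

    centers = np.empty((n_target, 3))
    radii = np.empty(n_target)
    n_placed = 0
    attempts = 0
    max_attempts = max_attempts_factor * n_target
    ext = np.asarray(extent)
    while n_placed < n_target and attempts < max_attempts:
        attempts += 1
        r = rng.normal(radius_mean, radius_sd)
        if r <= 1.0:
            continue
        if 2 * r > min(extent):
            continue
        c = rng.uniform(r, ext - r)
        if n_placed:
            d = np.linalg.norm(centers[:n_placed] - c, axis=1)
            if np.any(d < radii[:n_placed] + r):
                continue
        s = rng.normal(shell_mean, shell_sd)
        s = min(max(s, 1e-3), r)
        centers[n_placed] = c
        radii[n_placed] = r
        vol.neurons.append(Neuron(id=n_placed, center=c.copy(), radius=float(r), shell_width=float(s)))
        n_placed += 1
    if n_placed < n_target:
        warnings.warn(
            f"placement budget exhausted: placed {n_placed}/{n_target} neurons",
            stacklevel=2,
        )
    return vol


def build_synchronicity(
    n_neurons: int,
    common_input_probability: float = COMMON_INPUT_PROB,
    rng: np.random.Generator | None = None,
) -> SynchronicityMatrix:
    """Independent Bernoulli links on unordered pairs, symmetrized."""
    if not (0.0 <= common_input_probability <= 1.0):
        raise ValueError("common_input_probability must be in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    m = np.zeros((n_neurons, n_neurons), dtype=np.int8)
    iu = np.triu_indices(n_neurons, k=1)
    links = (rng.random(len(iu[0])) < common_input_probability).astype(np.int8)
    m[iu] = links
    m += m.T
    return SynchronicityMatrix(matrix=m, common_input_probability=common_input_probability)


def simulate_spikes(
    sync: SynchronicityMatrix,
    rho: float = RHO_DEFAULT,
    n_frames: int = 1500,
    rng: np.random.Generator | None = None,
    common_fraction: float = COMMON_FRACTION_DEFAULT,
) -> np.ndarray:
    """Per-frame spike counts as private + shared Poisson processes.

    Each linked neuron (any nonzero row of the synchronicity matrix) receives
    an independent thinning — keep probability equal to the common-input
    probability ``p`` — of one shared Poisson source, carrying a fraction
    ``common_fraction`` (q) of its mean rate; the remainder is an independent
    private Poisson process, so the total mean count per frame is exactly
    ``rho``. Spike-count correlation between two linked neurons is q·p
    analytically; the default q = 0.105 makes p·q = 0.084 at p = 0.8.
    """
    if rho < 0:
        raise ValueError("rho must be non-negative")
    if not (0.0 <= common_fraction < 1.0):
        raise ValueError("common_fraction must be in [0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    n = sync.matrix.shape[0]
    if rho == 0 or n == 0:
        return np.zeros((n, n_frames), dtype=np.int64)

    p = sync.common_input_probability
    linked = sync.matrix.sum(axis=1) > 0
    spikes = np.zeros((n, n_frames), dtype=np.int64)
    q = common_fraction
    if p > 0 and q > 0:
        # shared source; each receiver keeps events with prob p so that the
        # received rate is q*rho and cov between receivers is q*rho*p
        lam_common = q * rho / p
        source = rng.poisson(lam_common, size=n_frames)
        for i in range(n):
            if linked[i]:
                spikes[i] = rng.binomial(source, p)
        private_rate = np.where(linked, (1.0 - q) * rho, rho)
    else:
        private_rate = np.full(n, rho)
    spikes += rng.poisson(private_rate[:, None], size=(n, n_frames))
    return spikes


def spikes_to_calcium(spikes: np.ndarray, gamma: float = GAMMA_DEFAULT) -> np.ndarray:
    """AR(1) convolution of spikes: c_t = gamma*c_{t-1} + s_t, c_0 = s_0."""
    if not (0.0 <= gamma < 1.0):
        raise ValueError("gamma must be in [0, 1)")
    s = np.atleast_2d(np.asarray(spikes, dtype=float))
    c = np.empty_like(s)
    c[:, 0] = s[:, 0]
    for t in range(1, s.shape[1]):
        c[:, t] = gamma * c[:, t - 1] + s[:, t]
    return c if np.asarray(spikes).ndim == 2 else c[0]


def calcium_to_fluorescence(
    calcium: np.ndarray,
    baseline: float = 0.0,
    amplitude: float = 1500.0,
    hill_n: float = 1.0,
    kd: float = 1.0,
    noise_var: float = 0.05,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Hill saturation of calcium plus additive Gaussian noise.

    Noise-free value: ``baseline + amplitude * c**n / (c**n + kd**n)``.
    """
    if amplitude <= 0 or kd <= 0 or hill_n <= 0:
        raise ValueError("amplitude, kd, hill_n must be positive")
    if noise_var < 0:
        raise ValueError("noise_var must be non-negative")
    c = np.asarray(calcium, dtype=float)
    cn = np.power(c, hill_n)
    f = baseline + amplitude * cn / (cn + kd**hill_n)
    if noise_var > 0:
        rng = np.random.default_rng() if rng is None else rng
        f = f + rng.normal(0.0, np.sqrt(noise_var), size=f.shape)
    return f


def simulate_activity(
    n_neurons: int,
    n_frames: int = 1500,
    frame_rate: float = 5.0,
    rho: float = RHO_DEFAULT,
    gamma: float = GAMMA_DEFAULT,
    common_input_probability: float = COMMON_INPUT_PROB,
    common_fraction: float = COMMON_FRACTION_DEFAULT,
    hill: dict | None = None,
    rng: np.random.Generator | None = None,
) -> ActivitySet:
    """End-to-end ground-truth activity at the default generative parameters.

    ``rho`` is the mean firing rate in spikes/s and is converted to a
    per-frame Poisson rate at ``frame_rate``. (At 0.4 spikes/frame instead,
    calcium never returns to rest at gamma = 0.7 and the 5 Hz frame clock,
    and trace baselines become activity-dominated; 0.4 spikes/s gives the
    sparse-transient regime calcium imaging operates in.) The mean pairwise
    correlation of the ground truth is rate-independent (= p*q) either way.
    """
    rng = np.random.default_rng() if rng is None else rng
    hill = dict(HILL_PARAMS) if hill is None else {**HILL_PARAMS, **hill}
    sync = build_synchronicity(n_neurons, common_input_probability, rng)
    spikes = simulate_spikes(sync, rho / frame_rate, n_frames, rng, common_fraction)
    calcium = spikes_to_calcium(spikes, gamma)
    fluor = calcium_to_fluorescence(calcium, rng=rng, **hill)
    return ActivitySet(
        frame_rate=frame_rate,
        spikes=spikes,
        calcium=calcium,
        fluorescence=fluor,
        params=dict(
            rho=rho,
            gamma=gamma,
            common_input_probability=common_input_probability,
            common_fraction=common_fraction,
            **hill,
        ),
    )


def simulate_state_session(
    n_neurons: int,
    state_sequence: np.ndarray,
    rate_Q: float = 0.1,
    rate_A: float = 0.8,
    module_spec: list[list[int]] | None = None,
    rng: np.random.Generator | None = None,
    gamma: float = GAMMA_DEFAULT,
    frame_rate: float = 5.0,
    module_common_fraction: float = 0.7,
) -> tuple[ActivitySet, np.ndarray]:
    """Activity with planted state-modulated modules, for analysis fixtures.

    Neurons listed in ``module_spec`` fire at ``rate_Q`` during state-0 frames
    and ``rate_A`` during state-1 frames; a fraction of their rate comes from
    a module-shared Poisson process so module members co-fluctuate. All other
    neurons fire at ``rate_Q`` throughout. Returns the activity and the state
    labels it was generated from.
    """
    state = np.asarray(state_sequence).astype(int)
    if state.size == 0:
        raise ValueError("state_sequence must be non-empty")
    if rate_Q < 0 or rate_A < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng() if rng is None else rng
    n_frames = state.size
    module_spec = module_spec or []
    in_module = np.zeros(n_neurons, dtype=bool)
    for members in module_spec:
        in_module[np.asarray(members, dtype=int)] = True

    rate_t = np.where(state == 1, rate_A, rate_Q)  # (n_frames,)
    spikes = np.zeros((n_neurons, n_frames), dtype=np.int64)
    qm = module_common_fraction
    for members in module_spec:
        members = np.asarray(members, dtype=int)
        shared = rng.poisson(qm * rate_t)
        for i in members:
            spikes[i] = shared + rng.poisson((1 - qm) * rate_t)
    solo = ~in_module
    spikes[solo] = rng.poisson(rate_Q, size=(int(solo.sum()), n_frames))

    calcium = spikes_to_calcium(spikes, gamma)
    fluor = calcium_to_fluorescence(calcium, rng=rng, **HILL_PARAMS)
    act = ActivitySet(
        frame_rate=frame_rate,
        spikes=spikes,
        calcium=calcium,
        fluorescence=fluor,
        params=dict(rate_Q=rate_Q, rate_A=rate_A, gamma=gamma, modules=module_spec),
    )
    return act, state
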