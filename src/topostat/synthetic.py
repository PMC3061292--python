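"""Synthetic datasets and null image volumes with known ground truth.

Every downstream stage — interpolation, smoothing, the GLM, and the
random-field correction — is validated against data from this module:

* ``gen_montage``: quasi-uniform sensors on an upper hemisphere
  (9 cm head radius) with fiducials and a flattened 2D layout;
* ``gen_dataset``: trials built as a sum of effects (signed Gaussian
  scalp topographies x Gaussian temporal envelopes, optionally carrying
  a phase-locked or random-phase oscillation) plus spatially correlated
  AR(1) noise;
* ``gen_null_volume``: unit-variance smooth Gaussian random fields of
  known FWHM for calibrating topological inference.

All generators are pure functions of their spec and a single integer
seed; sub-streams are derived deterministically via ``SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from topostat.core_data import ChannelLayout2D, EpochedDataset
from topostat.geometry import FiducialSet, project_to_layout

HEAD_RADIUS_M = 0.09


@dataclass
class EffectSpec:
    """One experimental effect entering every trial of selected conditions.

    The scalp pattern is a sum of signed Gaussian bumps centred at
    ``centers`` (2D layout coordinates) with width ``spread`` (layout
    units); ``center_signs`` give each bump's polarity, so a +/- pair
    mimics a dipolar topography.  The time course is a Gaussian envelope
    with the stated latency and FWHM (ms); if ``freq_hz`` is set the
    envelope multiplies a sinusoid whose phase is fixed across trials
    when ``phase_locked`` or uniform-random per trial otherwise.
    ``condition_weights`` scales the effect per condition (0 = absent).
    """

    centers: np.ndarray  # (k, 2) layout coordinates
    spread: float
    amplitude: float
    latency_ms: float
    temporal_fwhm_ms: float
    condition_weights: dict[str, float]
    center_signs: np.ndarray | None = None
    freq_hz: float | None = None
    phase_locked: bool = True

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.center_signs is None:
            self.center_signs = np.ones(len(self.centers))
        else:
            self.center_signs = np.asarray(self.center_signs, dtype=float)
        if self.spread <= 0:
            raise ValueError("effect field 'spread' must be > 0")
        if self.temporal_fwhm_ms <= 0:
            raise ValueError("effect field 'temporal_fwhm_ms' must be > 0")
        if not all(np.isfinite(list(self.condition_weights.values()))):
            raise ValueError("effect field 'condition_weights' must be finite")


@dataclass
class NoiseSpec:
    """Sensor noise: AR(1) in time, exponentially correlated across the layout.

    ``sd`` is the marginal (stationary) standard deviation per channel;
    ``spatial_corr_length`` is the e-folding distance of the
    exp(-d/length) correlation over 2D layout distance; ``ar_coef`` is
    the lag-one autoregressive coefficient.
    """

    sd: float = 1.0
    spatial_corr_length: float = 0.3
    ar_coef: float = 0.3

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("noise field 'sd' must be > 0")
        if self.spatial_corr_length <= 0:
            raise ValueError("noise field 'spatial_corr_length' must be > 0")
        if not -1.0 < self.ar_coef < 1.0:
            raise ValueError("noise field 'ar_coef' must lie in (-1, 1)")


@dataclass
class SimulationSpec:
    """Full recipe for one synthetic epoched dataset."""

    n_trials_per_condition: dict[str, int]
    n_channels: int = 32
    dt_ms: float = 4.0
    epoch_ms: tuple[float, float] = (-100.0, 400.0)
    effects: list[EffectSpec] = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 4:
            raise ValueError("spec field 'n_channels' must be >= 4")
        if self.dt_ms <= 0:
            raise ValueError("spec field 'dt_ms' must be > 0")
        if self.epoch_ms[1] <= self.epoch_ms[0]:
            raise ValueError("spec field 'epoch_ms' must be an increasing interval")
        for label, n in self.n_trials_per_condition.items():
            if n < 1:
                raise ValueError(f"spec requires >= 1 trial for condition {label!r}")


def gen_montage(n_channels: int, seed: int = 0):
    """Quasi-uniform sensors on an upper hemisphere plus fiducials.

    Sensors follow a Fibonacci spiral on the upper half of a 9 cm
    sphere (head coordinates: x right, y anterior, z up), jittered
    slightly so no montage is perfectly symmetric; the 2D layout is the
    azimuthal-equidistant projection.  Fiducials are the nasion and the
    left/right preauricular analogues on the sphere's equator.

    Returns ``(positions3d, layout2d, fiducials)``.
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA1]))
    i = np.arange(n_channels)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    # upper hemisphere: z in (0.15, 1) keeps sensors off the equator rim
    z = 0.15 + (0.995 - 0.15) * (i + 0.5) / n_channels
    azim = 2.0 * np.pi * i / golden + rng.uniform(0, 2 * np.pi)
    r_xy = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pts = np.stack([r_xy * np.cos(azim), r_xy * np.sin(azim), z], axis=1)
    pts *= HEAD_RADIUS_M
    layout = project_to_layout(pts, head_center=np.zeros(3))
    fids = FiducialSet(
        {
            "nasion": np.array([0.0, HEAD_RADIUS_M, 0.0]),
            "lpa": np.array([-HEAD_RADIUS_M, 0.0, 0.0]),
            "rpa": np.array([HEAD_RADIUS_M, 0.0, 0.0]),
        }
    )
    return pts, layout, fids


def _effect_topography(effect: EffectSpec, layout: ChannelLayout2D) -> np.ndarray:
    pos = layout.positions2d
    topo = np.zeros(pos.shape[0])
    for center, sign in zip(effect.centers, effect.center_signs):
        d2 = np.sum((pos - center) ** 2, axis=1)
        topo += sign * np.exp(-d2 / (2.0 * effect.spread**2))
    return effect.amplitude * topo


def _effect_envelope(effect: EffectSpec, t_ms: np.ndarray) -> np.ndarray:
    sigma = effect.temporal_fwhm_ms / np.sqrt(8.0 * np.log(2.0))
    return np.exp(-((t_ms - effect.latency_ms) ** 2) / (2.0 * sigma**2))


def gen_dataset(spec: SimulationSpec) -> EpochedDataset:
    """Simulate an epoched dataset per the spec: sum of effects plus noise."""
    ss = np.random.SeedSequence([int(spec.seed), 0xD5])
    rng_noise, rng_phase = [np.random.default_rng(s) for s in ss.spawn(2)]
    _, layout, _ = gen_montage(spec.n_channels, seed=spec.seed)

    t = np.arange(spec.epoch_ms[0], spec.epoch_ms[1] + 0.5 * spec.dt_ms, spec.dt_ms)
    n_time = t.size
    labels: list[str] = []
    for cond, n in spec.n_trials_per_condition.items():
        labels += [cond] * n
    n_trials = len(labels)

    data = np.zeros((n_trials, spec.n_channels, n_time))

    # deterministic per-effect topographies and envelopes
    for effect in spec.effects:
        topo = _effect_topography(effect, layout)
        env = _effect_envelope(effect, t)
        if effect.freq_hz is None:
            course = np.broadcast_to(env, (n_trials, n_time)).copy()
        else:
            omega = 2.0 * np.pi * effect.freq_hz / 1000.0  # rad per ms
            if effect.phase_locked:
                phases = np.zeros(n_trials)
            else:
                phases = rng_phase.uniform(0.0, 2.0 * np.pi, size=n_trials)
            course = env[None, :] * np.cos(omega * (t[None, :] - effect.latency_ms)
                                           + phases[:, None])
        w = np.array([effect.condition_weights.get(lab, 0.0) for lab in labels])
        data += w[:, None, None] * topo[None, :, None] * course[:, None, :]

    # noise: spatial chol factor once, AR(1) recursion over time
    ns = spec.noise
    pos2d = layout.positions2d
    d = np.sqrt(np.sum((pos2d[:, None] - pos2d[None, :]) ** 2, axis=-1))
    K = np.exp(-d / ns.spatial_corr_length) + 1e-8 * np.eye(spec.n_channels)
    L = np.linalg.cholesky(K)
    phi = ns.ar_coef
    innov = rng_noise.standard_normal((n_trials, n_time, spec.n_channels))
    innov = innov @ L.T  # correlated across channels, unit marginal variance
    noise = np.empty((n_trials, n_time, spec.n_channels))
    noise[:, 0] = innov[:, 0]
    scale = np.sqrt(1.0 - phi**2)
    for k in range(1, n_time):
        noise[:, k] = phi * noise[:, k - 1] + scale * innov[:, k]
    data += ns.sd * np.transpose(noise, (0, 2, 1))

    names = [f"CH{i:03d}" for i in range(spec.n_channels)]
    return EpochedDataset(
        data=data,
        time_axis=t,
        channel_names=names,
        channel_types=["EEG"] * spec.n_channels,
        condition_labels=labels,
        layout=layout,
    )


def gen_null_volume(
    shape: tuple[int, ...], fwhm_voxels: float | tuple[float, ...], seed: int = 0
) -> np.ndarray:
    """Unit-variance stationary smooth Gaussian random field of known FWHM.

    White Gaussian noise on a padded lattice is convolved with a
    separable Gaussian kernel whose FWHM in voxels is ``fwhm_voxels``
    per dimension, cropped back to ``shape`` so every retained voxel has
    full kernel support (no edge effects, no periodic wrap-around), and
    divided by the exact post-convolution standard deviation so the
    pointwise variance is 1.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 4 for s in shape):
        raise ValueError("all dimensions must be >= 4")
    fwhm = np.broadcast_to(np.asarray(fwhm_voxels, dtype=float), (len(shape),))
    if np.any(fwhm < 0):
        raise ValueError("fwhm must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5F]))
    sigmas = fwhm / np.sqrt(8.0 * np.log(2.0))
    radii = [int(np.ceil(4.0 * s)) for s in sigmas]
    padded = tuple(n + 2 * r for n, r in zip(shape, radii))
    vol = rng.standard_normal(padded)
    if np.all(fwhm == 0):
        return vol[tuple(slice(r, r + n) for r, n in zip(radii, shape))].copy()
    var = 1.0
    for axis, (s, r, n) in enumerate(zip(sigmas, radii, padded)):
        if s == 0:
            continue
        x = np.arange(-r, r + 1)
        k = np.exp(-(x**2) / (2.0 * s**2))
        k /= k.sum()
        var *= np.sum(k**2)
        kshape = [1] * len(padded)
        kshape[axis] = k.size
        vol = fftconvolve(vol, k.reshape(kshape), mode="same", axes=axis)
    out = vol[tuple(slice(r, r + n) for r, n in zip(radii, shape))]
    return np.ascontiguousarray(out) / np.sqrt(var)
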