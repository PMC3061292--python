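"""Morlet wavelet time-frequency decomposition and its 2D/3D reductions.

Power is estimated per trial, channel and frequency as the squared
magnitude of the convolution with a complex Morlet wavelet

    w(t; f) = A * exp(i 2 pi f t) * exp(-t^2 / (2 sigma_t^2)),
    sigma_t = n_cycles / (2 pi f),

normalized to unit total energy and truncated at 5 sigma_t.  Epoch edges
are handled by reflection padding; samples within 5 sigma_t of either
edge are flagged as edge-contaminated in the result.

Because topological inference is limited to three dimensions, the 4D
(space x space x time x frequency) power array is reduced either by
averaging over channels (giving 2D time-frequency images) or by
averaging over a frequency band (giving power waveforms stored as an
ordinary time-domain dataset, ready for image export).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from topostat.core_data import ChannelLayout2D, EpochedDataset
from topostat.image_export import StatImage


@dataclass(frozen=True)
class MorletSpec:
    """Frequency grid (Hz, strictly increasing) and wavelet width in cycles.

    ``n_cycles`` trades temporal for spectral resolution
    (sigma_t = n_cycles / (2 pi f)); values above 5 keep the wavelet
    well-behaved, and 7 is the default.
    """

    frequencies: np.ndarray
    n_cycles: float = 7.0

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequencies must be a non-empty 1D array")
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        object.__setattr__(self, "frequencies", f)

    @classmethod
    def linear(cls, f_min: float, f_max: float, df: float = 1.0,
               n_cycles: float = 7.0) -> "MorletSpec":
        return cls(np.arange(f_min, f_max + 0.5 * df, df), n_cycles)


@dataclass
class TFDecomposition:
    """Power array (n_trials, n_channels, n_freq, n_time) with axes."""

    power: np.ndarray
    frequencies: np.ndarray
    time_axis: np.ndarray
    channel_names: list[str]
    channel_types: list[str]
    condition_labels: list[str]
    layout: ChannelLayout2D
    bad_channels: np.ndarray
    rejected_trials: np.ndarray
    edge_mask: np.ndarray  # (n_freq, n_time) True where edge-contaminated

    @property
    def dt_ms(self) -> float:
        return float(np.median(np.diff(self.time_axis)))


def morlet_wavelet(freq_hz: float, dt_ms: float, n_cycles: float = 7.0) -> np.ndarray:
    """Complex Morlet wavelet sampled at dt_ms, unit energy, 5-sigma support."""
    sigma_t_ms = 1000.0 * n_cycles / (2.0 * np.pi * freq_hz)
    half = max(int(np.ceil(5.0 * sigma_t_ms / dt_ms)), 1)
    t = np.arange(-half, half + 1) * dt_ms
    w = np.exp(2j * np.pi * freq_hz * t / 1000.0) * np.exp(-(t**2) / (2 * sigma_t_ms**2))
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def morlet_transform(ds: EpochedDataset, spec: MorletSpec) -> TFDecomposition:
    """Morlet power per trial, channel, frequency and time sample."""
    nyquist = ds.sampling_rate_hz / 2.0
    if spec.frequencies[-1] >= nyquist:
        raise ValueError(
            f"highest frequency {spec.frequencies[-1]:g} Hz is at or above "
            f"Nyquist ({nyquist:g} Hz)"
        )
    n_tr, n_ch, n_t = ds.data.shape
    n_f = spec.frequencies.size
    power = np.empty((n_tr, n_ch, n_f, n_t))
    edge = np.zeros((n_f, n_t), dtype=bool)
    flat = ds.data.reshape(n_tr * n_ch, n_t)
    for j, f in enumerate(spec.frequencies):
        w = morlet_wavelet(f, ds.dt_ms, spec.n_cycles)
        half = (len(w) - 1) // 2
        pad = min(half, n_t - 1)
        padded = np.pad(flat, ((0, 0), (pad, pad)), mode="reflect")
        coef = fftconvolve(padded, np.conj(w[::-1])[None, :], mode="same", axes=1)
        coef = coef[:, pad: pad + n_t]
        power[:, :, j, :] = (np.abs(coef) ** 2).reshape(n_tr, n_ch, n_t)
        edge[j, :pad] = True
        edge[j, n_t - pad:] = True
        if half > pad:  # support exceeds the epoch: everything is edge
            edge[j, :] = True
    return TFDecomposition(
        power=power,
        frequencies=spec.frequencies.copy(),
        time_axis=ds.time_axis.copy(),
        channel_names=list(ds.channel_names),
        channel_types=list(ds.channel_types),
        condition_labels=list(ds.condition_labels),
        layout=ds.layout,
        bad_channels=ds.bad_channels.copy(),
        rejected_trials=ds.rejected_trials.copy(),
        edge_mask=edge,
    )


def tf_image_from_channels(
    tf: TFDecomposition, channels: list[str] | list[int] | None = None
) -> list[StatImage]:
    """Mean power over selected channels: one 2D freq x time image per trial.

    Selecting one channel is the common special case; all selected
    channels must be good.
    """
    if channels is None:
        idx = np.flatnonzero(~tf.bad_channels)
    else:
        idx = np.array(
            [tf.channel_names.index(c) if isinstance(c, str) else int(c)
             for c in channels]
        )
    if idx.size == 0:
        raise ValueError("empty channel selection")
    if np.any(tf.bad_channels[idx]):
        bad = [tf.channel_names[i] for i in idx if tf.bad_channels[i]]
        raise ValueError(f"selection includes bad channel(s): {bad}")
    df = float(np.median(np.diff(tf.frequencies))) if tf.frequencies.size > 1 else 1.0
    out = []
    for tr in range(tf.power.shape[0]):
        plane = tf.power[tr, idx].mean(axis=0)  # (n_freq, n_time)
        out.append(
            StatImage(
                plane, ("Hz", "ms"), (df, tf.dt_ms),
                (float(tf.frequencies[0]), float(tf.time_axis[0])),
                provenance={"trial": tr,
                            "condition": tf.condition_labels[tr]},
            )
        )
    return out


def band_average_to_dataset(
    tf: TFDecomposition, band_hz: tuple[float, float]
) -> EpochedDataset:
    """Average power over a frequency band, giving power waveforms.

    The result is an ordinary time-domain dataset (same channels,
    trials, labels and layout) whose samples are band-average power —
    reviewable and image-exportable like any other dataset.
    """
    f1, f2 = min(band_hz), max(band_hz)
    keep = (tf.frequencies >= f1) & (tf.frequencies <= f2)
    if not keep.any():
        raise ValueError("band does not intersect the frequency grid")
    data = tf.power[:, :, keep, :].mean(axis=2)
    return EpochedDataset(
        data=data,
        time_axis=tf.time_axis.copy(),
        channel_names=list(tf.channel_names),
        channel_types=list(tf.channel_types),
        condition_labels=list(tf.condition_labels),
        layout=tf.layout,
        bad_channels=tf.bad_channels.copy(),
        rejected_trials=tf.rejected_trials.copy(),
    )
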