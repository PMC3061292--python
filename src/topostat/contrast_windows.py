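"""Time-frequency window contrasts: Gaussian time weights and Morlet energy.

A contrast summarizes a multichannel (or multisource) trial ensemble
over one or more peristimulus time segments and an optional frequency
band, yielding one scalar per channel/source:

* band = 0: a weighted temporal average.  The weight vector is the
  indicator of the segment union convolved with a Gaussian of 8 ms
  FWHM and normalized to unit sum; a degenerate segment (t1 == t2)
  therefore reduces to a pure 8 ms-FWHM Gaussian around that instant.
  Note a response that changes polarity inside the window can average
  to zero — that is the point of offering the energy alternative.
* band > 0: Morlet wavelet projectors over the band accumulate
  Gaussian-weighted power ("energy") in the window.  Over a wide band
  this is equivalent to the sum of squared amplitudes in the time
  domain (Parseval).

Application modes for epoched data: ``evoked`` applies the projectors
to the trial average (phase-locked energy only), ``induced`` applies
them per trial and averages (capturing activity with no phase locking),
``trials`` returns one value per trial for parametric within-subject
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from topostat.timefreq import morlet_wavelet

#: FWHM (ms) of the Gaussian edge applied to time windows.
EDGE_FWHM_MS = 8.0

MODES = ("evoked", "induced", "trials")


@dataclass(frozen=True)
class TFContrastSpec:
    """Time segments (ms), frequency band (Hz) or 0, and application mode."""

    time_segments: tuple[tuple[float, float], ...]
    band_hz: tuple[float, float] | float = 0.0
    mode: str = "evoked"
    edge_fwhm_ms: float = EDGE_FWHM_MS

    def __post_init__(self):
        segs = tuple((float(a), float(b)) for a, b in self.time_segments)
        for a, b in segs:
            if b < a:
                raise ValueError(f"time segment [{a}, {b}] is reversed")
        object.__setattr__(self, "time_segments", segs)
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        band = self.band_hz
        if not np.isscalar(band):
            f1, f2 = band
            if not (0 < f1 <= f2):
                raise ValueError("frequency band must satisfy 0 < f1 <= f2")
            object.__setattr__(self, "band_hz", (float(f1), float(f2)))
        elif band != 0:
            object.__setattr__(self, "band_hz", (float(band), float(band)))

    @property
    def is_energy(self) -> bool:
        return self.band_hz != 0.0


@dataclass(frozen=True)
class TimeWindowWeights:
    """Unit-sum non-negative temporal weights over the epoch samples."""

    weights: np.ndarray
    time_axis: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "time_axis", np.asarray(self.time_axis, float))


def build_time_weights(
    segments, time_axis: np.ndarray, edge_fwhm_ms: float = EDGE_FWHM_MS
) -> TimeWindowWeights:
    """Gaussian-edged window weights over the epoch sampling grid.

    The indicator of the union of ``segments`` (inclusive, in
    peristimulus ms; a segment may be degenerate, t1 == t2) is convolved
    with a Gaussian of ``edge_fwhm_ms`` FWHM and normalized to unit sum.
    """
    t = np.asarray(time_axis, dtype=float)
    dt = float(np.median(np.diff(t)))
    if np.isscalar(segments[0]):
        segments = [segments]
    ind = np.zeros(t.size)
    any_overlap = False
    for a, b in segments:
        a, b = min(a, b), max(a, b)
        sel = (t >= a - dt / 2) & (t <= b + dt / 2)
        if sel.any():
            any_overlap = True
        ind[sel] = 1.0
    if not any_overlap:
        raise ValueError("no time segment overlaps the epoch")
    sigma = edge_fwhm_ms / np.sqrt(8.0 * np.log(2.0)) / dt  # in samples
    half = max(int(np.ceil(5.0 * sigma)), 1)
    x = np.arange(-half, half + 1)
    kern = np.exp(-(x**2) / (2.0 * sigma**2))
    w = np.convolve(ind, kern, mode="same")
    s = w.sum()
    if s <= 0:
        raise ValueError("window weights vanished on the epoch grid")
    return TimeWindowWeights(w / s, t)


def apply_time_contrast(series: np.ndarray, weights: TimeWindowWeights) -> np.ndarray:
    """Weighted temporal average sum_t g(t) x(t) along the last axis."""
    x = np.asarray(series, dtype=float)
    g = weights.weights
    if x.shape[-1] != g.size:
        raise ValueError(
            f"series has {x.shape[-1]} samples but weights have {g.size}"
        )
    return x @ g


def morlet_energy(
    series: np.ndarray,
    weights: TimeWindowWeights,
    band_hz: tuple[float, float],
    dt_ms: float,
    df_hz: float = 1.0,
    n_cycles: float = 7.0,
) -> np.ndarray:
    """Gaussian-weighted Morlet power summed over a band, per row.

    energy = sum_{f in band} sum_t g(t) |(x * w_f)(t)|^2, for ``series``
    of shape (..., n_time).
    """
    x = np.asarray(series, dtype=float)
    n_t = x.shape[-1]
    nyq = 500.0 / dt_ms
    f1, f2 = band_hz
    if f2 >= nyq:
        raise ValueError(f"band upper edge {f2:g} Hz is at or above Nyquist")
    freqs = np.arange(f1, f2 + 0.5 * df_hz, df_hz)
    g = weights.weights
    flat = x.reshape(-1, n_t)
    total = np.zeros(flat.shape[0])
    for f in freqs:
        w = morlet_wavelet(f, dt_ms, n_cycles)
        half = (len(w) - 1) // 2
        pad = min(half, n_t - 1)
        padded = np.pad(flat, ((0, 0), (pad, pad)), mode="reflect")
        coef = fftconvolve(padded, np.conj(w[::-1])[None, :], mode="same", axes=1)
        coef = coef[:, pad: pad + n_t]
        total += (np.abs(coef) ** 2) @ g
    return total.reshape(x.shape[:-1])


def apply_energy_contrast(
    trials: np.ndarray,
    spec: TFContrastSpec,
    time_axis: np.ndarray,
    df_hz: float = 1.0,
    n_cycles: float = 7.0,
) -> np.ndarray:
    """Windowed Morlet energy of a trial ensemble (n_trials, n_units, n_time).

    Returns shape (n_units,) for evoked/induced, (n_trials, n_units) for
    trials mode.  A zero band is routed to :func:`apply_time_contrast`
    on the trial average.
    """
    x = np.asarray(trials, dtype=float)
    if x.ndim != 3:
        raise ValueError("trials array must be (n_trials, n_units, n_time)")
    weights = build_time_weights(spec.time_segments, time_axis, spec.edge_fwhm_ms)
    dt = float(np.median(np.diff(time_axis)))
    if not spec.is_energy:
        avg = x.mean(axis=0)
        return apply_time_contrast(avg, weights)
    band = spec.band_hz
    if spec.mode == "evoked":
        return morlet_energy(x.mean(axis=0), weights, band, dt, df_hz, n_cycles)
    per_trial = morlet_energy(x, weights, band, dt, df_hz, n_cycles)
    if spec.mode == "trials":
        return per_trial
    return per_trial.mean(axis=0)  # induced
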