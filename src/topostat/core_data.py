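"""Containers and basic operations for epoched multichannel datasets.

An :class:`EpochedDataset` holds a ``trials x channels x time`` array
together with the metadata needed downstream: peristimulus time axis
(ms, 0 = stimulus onset), channel names/types, per-trial condition
labels, bad-channel and rejected-trial flags, and a flattened 2D sensor
layout used for scalp-map interpolation.

Datasets round-trip to disk as a ``data.npy`` array plus a JSON sidecar
holding every piece of metadata losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

CHANNEL_TYPES = ("EEG", "MEG", "MEGPLANAR", "LFP", "Other")

#: Channel types that participate in image export by default.
IMAGING_TYPES = ("EEG", "MEG", "MEGPLANAR")


@dataclass(frozen=True)
class ChannelLayout2D:
    """Flattened sensor positions on the unit head disc (apex at origin)."""

    positions2d: np.ndarray  # (n_channels, 2)

    def __post_init__(self):
        pos = np.asarray(self.positions2d, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("layout positions must be (n_channels, 2)")
        object.__setattr__(self, "positions2d", pos)

    @property
    def n_channels(self) -> int:
        return self.positions2d.shape[0]


@dataclass
class EpochedDataset:
    """Epoched multichannel time series with metadata.

    ``data`` has shape ``(n_trials, n_channels, n_time)``; ``time_axis``
    is in ms relative to stimulus onset and must be uniformly sampled.
    """

    data: np.ndarray
    time_axis: np.ndarray
    channel_names: list[str]
    channel_types: list[str]
    condition_labels: list[str]
    layout: ChannelLayout2D
    bad_channels: np.ndarray = None  # bool per channel
    rejected_trials: np.ndarray = None  # bool per trial

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        n_ch = self.data.shape[1] if self.data.ndim == 3 else 0
        n_tr = self.data.shape[0] if self.data.ndim == 3 else 0
        if self.bad_channels is None:
            self.bad_channels = np.zeros(n_ch, dtype=bool)
        else:
            self.bad_channels = np.asarray(self.bad_channels, dtype=bool)
        if self.rejected_trials is None:
            self.rejected_trials = np.zeros(n_tr, dtype=bool)
        else:
            self.rejected_trials = np.asarray(self.rejected_trials, dtype=bool)
        self.channel_names = list(self.channel_names)
        self.channel_types = list(self.channel_types)
        self.condition_labels = list(self.condition_labels)

    # -- shape accessors -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_time(self) -> int:
        return self.data.shape[2]

    @property
    def dt_ms(self) -> float:
        return float(np.median(np.diff(self.time_axis)))

    @property
    def sampling_rate_hz(self) -> float:
        return 1000.0 / self.dt_ms

    def good_channel_indices(self, types: Sequence[str] = IMAGING_TYPES) -> np.ndarray:
        """Indices of non-bad channels of the given types."""
        keep = np.array(
            [t in types and not bad
             for t, bad in zip(self.channel_types, self.bad_channels)]
        )
        return np.flatnonzero(keep)

    def retained_trial_indices(self, condition: str | None = None) -> np.ndarray:
        idx = np.flatnonzero(~self.rejected_trials)
        if condition is not None:
            idx = idx[[self.condition_labels[i] == condition for i in idx]]
        return idx

    @property
    def conditions(self) -> list[str]:
        """Distinct labels among retained trials, in first-appearance order."""
        seen: list[str] = []
        for i in self.retained_trial_indices():
            lab = self.condition_labels[i]
            if lab not in seen:
                seen.append(lab)
        return seen


@dataclass
class AveragedDataset:
    """Trial-averaged dataset: one waveform set per condition."""

    data: np.ndarray  # (n_conditions, n_channels, n_time)
    time_axis: np.ndarray
    channel_names: list[str]
    channel_types: list[str]
    condition_order: list[str]
    layout: ChannelLayout2D
    bad_channels: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.bad_channels is None:
            self.bad_channels = np.zeros(self.data.shape[1], dtype=bool)
        else:
            self.bad_channels = np.asarray(self.bad_channels, dtype=bool)

    @property
    def n_conditions(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_time(self) -> int:
        return self.data.shape[2]

    @property
    def dt_ms(self) -> float:
        return float(np.median(np.diff(self.time_axis)))

    def good_channel_indices(self, types: Sequence[str] = IMAGING_TYPES) -> np.ndarray:
        keep = np.array(
            [t in types and not bad
             for t, bad in zip(self.channel_types, self.bad_channels)]
        )
        return np.flatnonzero(keep)


@dataclass
class ValidationReport:
    ok: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def validate_dataset(ds: EpochedDataset) -> ValidationReport:
    """Check dataset invariants; returns a report, never raises or mutates.

    Checked: array dimensionality, metadata lengths, unique channel
    names, known channel types, a strictly increasing and uniform time
    axis, layout size and non-coincident layout positions, and flag
    lengths.
    """
    v: list[str] = []
    if ds.data.ndim != 3:
        v.append("data must be 3D (trials x channels x time)")
        return ValidationReport(False, v)
    n_tr, n_ch, n_t = ds.data.shape
    if len(ds.channel_names) != n_ch:
        v.append("channel name count mismatch")
    if len(set(ds.channel_names)) != len(ds.channel_names):
        v.append("duplicate channel names")
    if len(ds.channel_types) != n_ch:
        v.append("channel type count mismatch")
    else:
        unknown = sorted({t for t in ds.channel_types if t not in CHANNEL_TYPES})
        if unknown:
            v.append(f"unknown channel types: {unknown}")
    if len(ds.condition_labels) != n_tr:
        v.append("condition label count mismatch")
    if len(ds.time_axis) != n_t:
        v.append("time axis length mismatch")
    elif n_t >= 2:
        d = np.diff(ds.time_axis)
        if np.any(d <= 0):
            v.append("time axis not strictly increasing")
        else:
            dt = np.median(d)
            if np.max(np.abs(d - dt)) > 1e-9 * max(abs(dt), 1.0):
                v.append("time axis not uniformly sampled")
    if ds.layout.n_channels != n_ch:
        v.append("layout size mismatch")
    else:
        pos = ds.layout.positions2d
        d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if np.min(d2) <= 1e-18:
            v.append("coincident layout positions")
    if ds.bad_channels.shape != (n_ch,):
        v.append("bad channel flag length mismatch")
    if ds.rejected_trials.shape != (n_tr,):
        v.append("rejected trial flag length mismatch")
    return ValidationReport(not v, v)


def average_epochs(
    ds: EpochedDataset, conditions: Sequence[str] | None = None
) -> AveragedDataset:
    """Average retained trials per condition (arithmetic mean).

    Rejected trials are excluded.  Bad channels are averaged like any
    other channel — they are only dropped later, at image export.

    Raises ``ValueError`` if a requested condition has no retained trial.
    """
    if conditions is None:
        conditions = ds.conditions
    conditions = list(conditions)
    out = np.empty((len(conditions), ds.n_channels, ds.n_time))
    for k, cond in enumerate(conditions):
        idx = ds.retained_trial_indices(cond)
        if idx.size == 0:
            raise ValueError(f"no retained trials for condition {cond!r}")
        out[k] = ds.data[idx].mean(axis=0)
    return AveragedDataset(
        data=out,
        time_axis=ds.time_axis.copy(),
        channel_names=list(ds.channel_names),
        channel_types=list(ds.channel_types),
        condition_order=conditions,
        layout=ds.layout,
        bad_channels=ds.bad_channels.copy(),
    )


def hanning_taper(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Multiply a time series by a Hanning window spanning the epoch.

    The window is ``0.5*(1 - cos(2*pi*k/(N-1)))`` for ``k = 0..N-1`` so the
    endpoints are exactly zero; it down-weights baseline noise at the
    beginning and end of the trial.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    if n < 3:
        raise ValueError("hanning_taper requires at least 3 samples")
    k = np.arange(n)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * k / (n - 1)))
    shape = [1] * x.ndim
    shape[axis] = n
    return x * w.reshape(shape)


# ---------------------------------------------------------------------------
# On-disk container: data.npy + dataset.json sidecar
# ---------------------------------------------------------------------------

def save_dataset(ds: EpochedDataset | AveragedDataset, path: str | Path) -> Path:
    """Write a dataset directory: ``data.npy`` plus ``dataset.json``.

    The sidecar stores every metadata field so the round trip is
    lossless; the time axis is reconstructed from the sampling rate and
    the onset-relative start time.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "data.npy", ds.data)
    meta = {
        "kind": "averaged" if isinstance(ds, AveragedDataset) else "epoched",
        "sampling_rate_hz": 1000.0 / ds.dt_ms,
        "time_onset_ms": float(ds.time_axis[0]),
        "channel_names": list(ds.channel_names),
        "channel_types": list(ds.channel_types),
        "layout": np.asarray(ds.layout.positions2d).tolist(),
        "bad_channels": np.asarray(ds.bad_channels).astype(int).tolist(),
    }
    if isinstance(ds, AveragedDataset):
        meta["conditions"] = list(ds.condition_order)
    else:
        meta["conditions"] = list(ds.condition_labels)
        meta["rejected_trials"] = ds.rejected_trials.astype(int).tolist()
    with open(path / "dataset.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def load_dataset(path: str | Path) -> EpochedDataset | AveragedDataset:
    """Read a dataset directory written by :func:`save_dataset`."""
    path = Path(path)
    data = np.load(path / "data.npy")
    with open(path / "dataset.json") as fh:
        meta = json.load(fh)
    dt_ms = 1000.0 / meta["sampling_rate_hz"]
    t0 = meta["time_onset_ms"]
    time_axis = t0 + dt_ms * np.arange(data.shape[2])
    layout = ChannelLayout2D(np.asarray(meta["layout"], dtype=float))
    bad = np.asarray(meta["bad_channels"], dtype=bool)
    if meta["kind"] == "averaged":
        return AveragedDataset(
            data=data,
            time_axis=time_axis,
            channel_names=meta["channel_names"],
            channel_types=meta["channel_types"],
            condition_order=list(meta["conditions"]),
            layout=layout,
            bad_channels=bad,
        )
    return EpochedDataset(
        data=data,
        time_axis=time_axis,
        channel_names=meta["channel_names"],
        channel_types=meta["channel_types"],
        condition_labels=list(meta["conditions"]),
        layout=layout,
        bad_channels=bad,
        rejected_trials=np.asarray(meta["rejected_trials"], dtype=bool),
    )
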