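import numpy as np
import pytest

from topostat.core_data import ChannelLayout2D, EpochedDataset
from topostat.synthetic import (
    EffectSpec,
    NoiseSpec,
    SimulationSpec,
    gen_dataset,
    gen_montage,
)


@pytest.fixture(scope="session")
def montage32():
    """3D positions, 2D layout and fiducials for a 32-channel montage."""
    return gen_montage(32, seed=7)


@pytest.fixture()
def small_dataset(montage32):
    """Deterministic 12-trial, 16-channel dataset with a known ERP effect."""
    spec = SimulationSpec(
        n_trials_per_condition={"face": 6, "scrambled": 6},
        n_channels=16,
        dt_ms=4.0,
        epoch_ms=(-100.0, 300.0),
        effects=[
            EffectSpec(
                centers=np.array([[0.3, 0.2]]),
                spread=0.35,
                amplitude=3.0,
                latency_ms=150.0,
                temporal_fwhm_ms=60.0,
                condition_weights={"face": 1.0, "scrambled": 0.2},
            )
        ],
        noise=NoiseSpec(sd=0.5, spatial_corr_length=0.3, ar_coef=0.3),
        seed=11,
    )
    return gen_dataset(spec)


@pytest.fixture()
def tiny_dataset():
    """Hand-built 4-channel dataset with fully controlled values."""
    rng = np.random.default_rng(3)
    layout = ChannelLayout2D(
        np.array([[0.0, 0.0], [0.6, 0.0], [0.0, 0.6], [-0.5, -0.4]])
    )
    data = rng.standard_normal((5, 4, 11))
    return EpochedDataset(
        data=data,
        time_axis=np.arange(-20.0, 90.0, 10.0),
        channel_names=["C1", "C2", "C3", "C4"],
        channel_types=["EEG"] * 4,
        condition_labels=["a", "a", "b", "b", "b"],
        layout=layout,
    )
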