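import numpy as np
import pytest

from amda.eeg_io import Recording, WindowSet
from amda.model import ModelConfig, SeizureModel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def make_recording():
    """Factory for small deterministic recordings with arbitrary seizures."""

    def _make(duration_s=300.0, fs=32.0, n_channels=2, seizures=(), seed=0, patient_id="p0"):
        gen = np.random.default_rng(seed)
        n = int(round(duration_s * fs))
        signal = gen.standard_normal((n_channels, n))
        return Recording(
            signal=signal,
            fs=fs,
            channel_names=[f"CH{i}" for i in range(n_channels)],
            seizures=list(seizures),
            patient_id=patient_id,
        )

    return _make


@pytest.fixture
def tiny_model_cfg():
    """A few-parameter configuration for fast training tests."""
    return ModelConfig(
        conv_channels=(4, 6), attention_dim=8, gru_units=8,
        dropout=0.0, epochs=5, batch_size=16, seed=7,
    )


@pytest.fixture
def tiny_model(tiny_model_cfg):
    return SeizureModel(tiny_model_cfg, n_channels=2, window_samples=32)


@pytest.fixture
def separable_windows():
    """Linearly separable two-class windows: class 1 has a mean offset and a
    strong 3 Hz rhythm, class 0 is plain noise."""

    def _make(n=80, n_channels=2, samples=32, seed=0):
        gen = np.random.default_rng(seed)
        half = n // 2
        t = np.arange(samples) / samples
        x0 = gen.standard_normal((half, n_channels, samples))
        x1 = gen.standard_normal((n - half, n_channels, samples))
        x1 += 3.0 * np.sin(2 * np.pi * 4 * t)[None, None, :] + 1.0
        windows = np.concatenate([x0, x1])
        labels = np.concatenate([np.zeros(half, dtype=int), np.ones(n - half, dtype=int)])
        order = gen.permutation(n)
        return WindowSet(
            windows=windows[order],
            labels=labels[order],
            sources=[("p0", float(i)) for i in range(n)],
            window_s=1.0,
        )

    return _make
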