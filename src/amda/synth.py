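"""Seeded synthetic multichannel EEG-like recordings with seizure intervals.

The generator aims at *testability*, not physiology: background is a sum of
band-limited oscillations plus 1/f-shaped noise; seizure intervals add a
strong low-frequency rhythm with periodic sharp transients, so windows are
separable by band power once ``amplitude_gain`` is large enough.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .edf import write_edf_file
from .eeg_io import Recording, ValidationError, write_annotations

__all__ = ["SynthConfig", "generate_recording", "generate_dataset", "write_dataset", "add_noise"]

#: delta/theta/alpha/beta band edges (Hz) and amplitudes in 4:3:2:1 ratio (uV)
DEFAULT_BANDS: dict[str, tuple[float, float, float]] = {
    "delta": (1.0, 4.0, 20.0),
    "theta": (4.0, 8.0, 15.0),
    "alpha": (8.0, 13.0, 10.0),
    "beta": (13.0, 30.0, 5.0),
}


@dataclass
class SynthConfig:
    """Parameters for one synthetic recording."""

    n_channels: int = 18
    fs: float = 256.0
    duration_s: float = 300.0
    seizure_intervals: list[tuple[float, float]] = field(default_factory=list)
    background_spectrum: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    rhythm_hz: float = 3.0
    amplitude_gain: float = 3.0
    spike_rate_hz: float = 1.0
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1 or self.fs <= 0 or self.duration_s <= 0:
            raise ValidationError("n_channels, fs and duration_s must be positive")
        if self.amplitude_gain <= 1:
            raise ValidationError("amplitude_gain must exceed 1 for separable seizures")
        if self.fs <= 2 * self.rhythm_hz:
            raise ValidationError("fs must exceed twice the seizure rhythm frequency")
        ivs = sorted(self.seizure_intervals)
        for (s, e) in ivs:
            if not (0 <= s < e <= self.duration_s):
                raise ValidationError(f"seizure interval ({s}, {e}) outside [0, {self.duration_s}]")
        for (_, prev_e), (s, _) in zip(ivs, ivs[1:]):
            if s < prev_e:
                raise ValidationError("seizure intervals must not overlap")


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int, fs: float) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, unit-ish scale."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    shaping[0] = 0.0
    pink = np.fft.irfft(spec * shaping, n=n, axis=1)
    sd = pink.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def generate_recording(cfg: SynthConfig) -> Recording:
    """Render one recording from a :class:`SynthConfig`, deterministically."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    nyq = cfg.fs / 2
    signal = np.zeros((cfg.n_channels, n))

    # background: per band, a few sinusoids with per-channel random freq/phase
    for (f_lo, f_hi, amp) in cfg.background_spectrum.values():
        f_hi = min(f_hi, nyq * 0.95)
        if f_hi <= f_lo:
            continue
        n_comp = 3
        for _ in range(n_comp):
            freqs = rng.uniform(f_lo, f_hi, size=cfg.n_channels)
            phases = rng.uniform(0, 2 * np.pi, size=cfg.n_channels)
            signal += (amp / n_comp) * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])

    background_rms = float(np.sqrt(np.mean(signal**2))) or 1.0
    signal += 3.0 * _pink_noise(rng, cfg.n_channels, n, cfg.fs)
    if cfg.noise_sd > 0:
        signal += cfg.noise_sd * rng.standard_normal((cfg.n_channels, n))

    # seizures: rhythmic component + periodic sharp transients across channels.
    # One phase draw per recording keeps ictal morphology homogeneous across
    # intervals, which keeps the separability guarantee tight.
    intervals = sorted((float(s), float(e)) for s, e in cfg.seizure_intervals)
    phase = rng.uniform(0, 2 * np.pi, size=cfg.n_channels)
    for s, e in intervals:
        a = int(round(s * cfg.fs))
        b = int(round(e * cfg.fs))
        seg_t = t[a:b]
        rhythm = np.sin(2 * np.pi * cfg.rhythm_hz * seg_t[None, :] + phase[:, None])
        signal[:, a:b] += cfg.amplitude_gain * background_rms * rhythm
        if cfg.spike_rate_hz > 0:
            spike = _spike_train(seg_t - s, cfg.spike_rate_hz, cfg.fs)
            signal[:, a:b] += 0.8 * cfg.amplitude_gain * background_rms * spike[None, :]

    return Recording(
        signal=signal,
        fs=cfg.fs,
        channel_names=[f"SYN{i + 1:02d}" for i in range(cfg.n_channels)],
        seizures=intervals,
        patient_id=f"synth{cfg.seed:05d}",
    )


def _spike_train(rel_t: np.ndarray, rate_hz: float, fs: float) -> np.ndarray:
    """Periodic Gaussian-shaped sharp transients (~25 ms wide)."""
    out = np.zeros_like(rel_t)
    if len(rel_t) == 0:
        return out
    width = 0.0125
    for center in np.arange(0.0, rel_t[-1] + 1e-9, 1.0 / rate_hz):
        out += np.exp(-0.5 * ((rel_t - center) / width) ** 2)
    return out


def _place_intervals(
    rng: np.random.Generator,
    duration_s: float,
    target_s: float,
    min_len: float = 30.0,
    max_len: float = 90.0,
    align_s: float | None = None,
) -> list[tuple[float, float]]:
    """Random non-overlapping intervals totalling ~``target_s`` seconds."""
    intervals: list[tuple[float, float]] = []
    placed = 0.0
    attempts = 0
    # never exceed the target: cap each draw by the remaining budget and
    # stop once the remainder is below half a minimal interval
    while target_s - placed >= min_len * 0.5 and attempts < 200:
        attempts += 1
        length = min(rng.uniform(min_len, max_len), target_s - placed, duration_s)
        if align_s:
            length = max(align_s, round(length / align_s) * align_s)
        start_max = duration_s - length
        if start_max < 0:
            break
        start = rng.uniform(0, start_max)
        if align_s:
            start = round(start / align_s) * align_s
            start = min(start, duration_s - length)
        cand = (start, start + length)
        if any(not (cand[1] <= s or cand[0] >= e) for s, e in intervals):
            continue
        intervals.append(cand)
        placed += length
    return sorted(intervals)


def generate_dataset(
    n_recordings: int,
    cfg_template: SynthConfig,
    seizure_fraction: float = 0.1,
    seed: int = 0,
    align_s: float | None = None,
) -> list[Recording]:
    """Generate ``n_recordings`` recordings with ~``seizure_fraction`` of the
    total duration inside annotated seizure intervals.

    Per-recording seeds are derived from ``seed`` via ``SeedSequence``;
    ``align_s`` snaps interval boundaries to a grid (handy for making
    window labels unambiguous in fixtures).
    """
    if not 0 <= seizure_fraction <= 1:
        raise ValidationError("seizure_fraction must be in [0, 1]")
    seqs = np.random.SeedSequence(seed).spawn(n_recordings)
    recordings = []
    for i, seq in enumerate(seqs):
        child_seed = int(seq.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(child_seed)
        target = seizure_fraction * cfg_template.duration_s
        intervals = (
            _place_intervals(rng, cfg_template.duration_s, target, align_s=align_s)
            if target > 0
            else []
        )
        cfg = replace(
            cfg_template,
            seizure_intervals=intervals,
            seed=child_seed + 1,
        )
        rec = generate_recording(cfg)
        rec.patient_id = f"synth{i:03d}"
        recordings.append(rec)
    return recordings


def write_dataset(recordings: list[Recording], out_dir) -> list[tuple[str, str]]:
    """Write recordings as EDF + plain-text annotation sidecars.

    Returns the list of (edf_path, annotation_path) pairs.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    pairs = []
    for rec in recordings:
        edf_path = os.path.join(out_dir, f"{rec.patient_id}.edf")
        ann_path = os.path.join(out_dir, f"{rec.patient_id}.seizures.txt")
        write_edf_file(edf_path, rec.signal, rec.fs, rec.channel_names, patient_id=rec.patient_id)
        write_annotations(ann_path, rec.seizures)
        pairs.append((edf_path, ann_path))
    return pairs


def add_noise(
    windows: np.ndarray,
    noise_sd: float,
    drift_amp: float = 0.0,
    fs: float = 256.0,
    seed: int = 0,
) -> np.ndarray:
    """Evaluation-time corruption: broadband noise plus slow baseline drift.

    Used by the robustness probe; never applied during training.
    """
    rng = np.random.default_rng(seed)
    out = np.array(windows, dtype=np.float64, copy=True)
    if noise_sd > 0:
        out += noise_sd * rng.standard_normal(out.shape)
    if drift_amp > 0:
        n = out.shape[-1]
        t = np.arange(n) / fs
        freqs = rng.uniform(0.05, 0.3, size=out.shape[:-1])
        phases = rng.uniform(0, 2 * np.pi, size=out.shape[:-1])
        out += drift_amp * np.sin(2 * np.pi * freqs[..., None] * t + phases[..., None])
    return out
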