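"""EEG recordings, seizure annotations, windowing, splitting, balancing.

All time intervals are half-open ``[start, end)`` in seconds. Window ``i``
covers ``[i * stride, i * stride + window_s)`` of its source recording.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .edf import EdfError, read_edf_file

__all__ = [
    "Recording",
    "WindowSet",
    "Normalizer",
    "ValidationError",
    "read_annotations",
    "write_annotations",
    "read_edf",
    "parse_chbmit_summary",
    "segment",
    "split",
    "balance",
]


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


def _normalize_intervals(intervals) -> list[tuple[float, float]]:
    ivs = sorted((float(s), float(e)) for s, e in intervals)
    merged: list[tuple[float, float]] = []
    for s, e in ivs:
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class Recording:
    """A multichannel recording with seizure-interval annotations.

    Attributes
    ----------
    signal : ndarray, shape (channels, samples)
        Raw signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    seizures : list of (start_s, end_s)
        Half-open seizure intervals in seconds; normalized to be sorted
        and non-overlapping.
    patient_id : str
    """

    signal: np.ndarray
    fs: float
    channel_names: list[str]
    seizures: list[tuple[float, float]] = field(default_factory=list)
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2 or self.signal.shape[0] < 1:
            raise ValidationError("signal must be [channels x samples] with >= 1 channel")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValidationError("channel_names length must match channel count")
        dur = self.duration_s
        for s, e in self.seizures:
            if not (0 <= s < e <= dur + 1e-9):
                raise ValidationError(
                    f"seizure interval ({s}, {e}) outside recording of {dur:.3f} s"
                )
        self.seizures = _normalize_intervals(self.seizures)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs


@dataclass
class WindowSet:
    """Stacked fixed-length windows with binary (or soft) labels.

    ``sources`` keeps per-window provenance as ``(patient_id, start_s)``.
    """

    windows: np.ndarray  # (n_windows, channels, window_samples)
    labels: np.ndarray  # (n_windows,)
    sources: list[tuple[str, float]]
    window_s: float

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.windows.ndim != 3:
            raise ValidationError("windows must be [n x channels x samples]")
        if len(self.labels) != len(self.windows) or len(self.sources) != len(self.windows):
            raise ValidationError("windows, labels and sources must align")

    def __len__(self) -> int:
        return len(self.windows)

    def subset(self, idx) -> "WindowSet":
        idx = np.asarray(idx, dtype=int)
        return WindowSet(
            windows=self.windows[idx],
            labels=self.labels[idx],
            sources=[self.sources[i] for i in idx],
            window_s=self.window_s,
        )

    @staticmethod
    def concatenate(parts: list["WindowSet"]) -> "WindowSet":
        parts = [p for p in parts if len(p) > 0]
        if not parts:
            raise ValidationError("nothing to concatenate")
        if len({p.windows.shape[1] for p in parts}) != 1:
            raise ValidationError("all parts must share one channel count")
        return WindowSet(
            windows=np.concatenate([p.windows for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            sources=[s for p in parts for s in p.sources],
            window_s=parts[0].window_s,
        )


# ---------------------------------------------------------------------------
# annotation I/O


def read_annotations(path) -> list[tuple[float, float]]:
    """Parse a plain-text annotation file: one ``start_s end_s`` per line.

    Blank lines and ``#`` comments are ignored.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: expected 'start_s end_s', got {line!r}")
            s, e = float(parts[0]), float(parts[1])
            if not s < e:
                raise ValidationError(f"{path}:{lineno}: start must precede end")
            out.append((s, e))
    return out


def write_annotations(path, seizures) -> None:
    with open(path, "w") as fh:
        fh.write("# seizure intervals, half-open [start_s end_s)\n")
        for s, e in seizures:
            fh.write(f"{s:.6g} {e:.6g}\n")


def parse_chbmit_summary(path) -> dict[str, list[tuple[float, float]]]:
    """Parse the documented subset of a CHB-MIT ``-summary.txt`` file.

    Returns a mapping from EDF file name to seizure intervals. Only the
    ``File Name`` / ``Seizure [N ]Start Time`` / ``Seizure [N ]End Time``
    line forms are understood.
    """
    result: dict[str, list[tuple[float, float]]] = {}
    current: str | None = None
    pending_start: float | None = None
    start_re = re.compile(r"Seizure(?: \d+)? Start Time:\s*(\d+(?:\.\d+)?)\s*sec", re.I)
    end_re = re.compile(r"Seizure(?: \d+)? End Time:\s*(\d+(?:\.\d+)?)\s*sec", re.I)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.lower().startswith("file name:"):
                current = line.split(":", 1)[1].strip()
                result.setdefault(current, [])
                pending_start = None
                continue
            m = start_re.search(line)
            if m and current is not None:
                pending_start = float(m.group(1))
                continue
            m = end_re.search(line)
            if m and current is not None and pending_start is not None:
                result[current].append((pending_start, float(m.group(1))))
                pending_start = None
    return result


def read_edf(
    path,
    annotation_path=None,
    patient_id: str | None = None,
    required_channels: list[str] | None = None,
) -> Recording:
    """Read an EDF recording plus its plain-text seizure annotations.

    If ``required_channels`` is given, the recording must contain every
    listed channel (matched case-insensitively); channels are returned in
    the requested order and extras are dropped. A recording lacking the
    configured channel set raises :class:`ValidationError` so callers can
    skip it — mirroring the "consistent channels" selection rule.
    """
    try:
        signals = read_edf_file(path)
    except EdfError:
        raise
    except OSError as exc:
        raise EdfError(f"cannot read {path}: {exc}") from exc
    fs = signals[0].fs
    if any(abs(s.fs - fs) > 1e-9 for s in signals):
        raise EdfError(f"{path}: mixed sampling rates are unsupported")
    names = [s.label for s in signals]
    data = np.stack([s.data for s in signals])
    if required_channels is not None:
        lookup = {n.lower(): i for i, n in enumerate(names)}
        missing = [c for c in required_channels if c.lower() not in lookup]
        if missing:
            raise ValidationError(f"{path}: missing required channels {missing}")
        order = [lookup[c.lower()] for c in required_channels]
        data = data[order]
        names = [names[i] for i in order]
    seizures = read_annotations(annotation_path) if annotation_path is not None else []
    duration = data.shape[1] / fs
    for s, e in seizures:
        if e > duration + 1e-9:
            raise ValidationError(
                f"annotation ({s}, {e}) extends past recording end at {duration:.3f} s"
            )
    pid = patient_id if patient_id is not None else str(path)
    return Recording(signal=data, fs=fs, channel_names=names, seizures=seizures, patient_id=pid)


# ---------------------------------------------------------------------------
# windowing


def _seizure_sample_fraction(rec: Recording, start_idx: int, stop_idx: int) -> float:
    """Fraction of samples in [start_idx, stop_idx) lying inside a seizure.

    Sample k (at time k/fs) is ictal iff start <= k/fs < end for some
    annotated interval.
    """
    total = 0
    for s, e in rec.seizures:
        lo = int(np.ceil(s * rec.fs - 1e-9))
        hi = int(np.ceil(e * rec.fs - 1e-9))
        total += max(0, min(hi, stop_idx) - max(lo, start_idx))
    return total / (stop_idx - start_idx)


def segment(
    rec: Recording,
    window_s: float = 30.0,
    overlap_s: float = 0.0,
    label_rule: float = 0.5,
) -> WindowSet:
    """Cut a recording into fixed-length windows with fractional labeling.

    A window gets label 1 iff the fraction of its samples inside any
    seizure interval is >= ``label_rule``. The trailing partial window is
    discarded. Values are bit-identical slices of the source signal.
    """
    if window_s <= 0:
        raise ValidationError("window_s must be positive")
    if not 0 <= overlap_s < window_s:
        raise ValidationError("overlap_s must satisfy 0 <= overlap < window_s")
    if not 0 < label_rule <= 1:
        raise ValidationError("label_rule must be in (0, 1]")
    win = int(round(window_s * rec.fs))
    stride = int(round((window_s - overlap_s) * rec.fs))
    if stride < 1:
        raise ValidationError("stride shorter than one sample")
    n = (rec.n_samples - win) // stride + 1 if rec.n_samples >= win else 0
    if n <= 0:
        warnings.warn(
            f"recording {rec.patient_id!r} shorter ({rec.duration_s:.1f} s) than "
            f"one {window_s} s window; returning empty WindowSet",
            stacklevel=2,
        )
        return WindowSet(
            windows=np.empty((0, rec.n_channels, win)),
            labels=np.empty((0,), dtype=np.int64),
            sources=[],
            window_s=window_s,
        )
    starts = np.arange(n) * stride
    windows = np.stack([rec.signal[:, a : a + win] for a in starts])
    labels = np.array(
        [int(_seizure_sample_fraction(rec, a, a + win) >= label_rule) for a in starts],
        dtype=np.int64,
    )
    sources = [(rec.patient_id, float(a / rec.fs)) for a in starts]
    return WindowSet(windows=windows, labels=labels, sources=sources, window_s=window_s)


# ---------------------------------------------------------------------------
# splitting and balancing


def split(
    ws: WindowSet,
    train_frac: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
    by_patient: bool = False,
) -> tuple[WindowSet, WindowSet]:
    """Deterministic train/test partition of a WindowSet.

    Stratified mode preserves class proportions to within one window per
    class. ``by_patient`` instead assigns whole patients to one side
    (patient-disjoint evaluation); stratification is then best-effort.
    """
    if not 0 < train_frac < 1:
        raise ValidationError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(ws)
    labels = np.asarray(np.rint(ws.labels), dtype=int)
    if by_patient:
        patients = sorted({p for p, _ in ws.sources})
        order = rng.permutation(len(patients))
        n_train_pat = max(1, min(len(patients) - 1, int(round(train_frac * len(patients)))))
        train_pats = {patients[i] for i in order[:n_train_pat]}
        train_idx = np.array([i for i, (p, _) in enumerate(ws.sources) if p in train_pats], dtype=int)
        test_idx = np.array([i for i in range(n) if i not in set(train_idx)], dtype=int)
    elif stratified:
        classes = np.unique(labels)
        if len(classes) < 2:
            raise ValidationError("stratified split requires both classes present")
        train_parts, test_parts = [], []
        for c in classes:
            idx = np.flatnonzero(labels == c)
            idx = rng.permutation(idx)
            k = int(round(train_frac * len(idx)))
            k = min(max(k, 1), len(idx) - 1)
            train_parts.append(idx[:k])
            test_parts.append(idx[k:])
        train_idx = np.sort(np.concatenate(train_parts))
        test_idx = np.sort(np.concatenate(test_parts))
    else:
        order = rng.permutation(n)
        k = int(round(train_frac * n))
        train_idx = np.sort(order[:k])
        test_idx = np.sort(order[k:])
    return ws.subset(train_idx), ws.subset(test_idx)


def balance(ws: WindowSet, policy: str = "undersample", seed: int = 0) -> WindowSet:
    """Class balancing. ``undersample`` keeps every minority window and a
    seeded random subset of majority windows of equal count; ``none`` is
    the identity."""
    if policy == "none":
        return ws
    if policy != "undersample":
        raise ValidationError(f"unknown balance policy {policy!r}")
    labels = np.asarray(np.rint(ws.labels), dtype=int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("undersample requires both classes present")
    rng = np.random.default_rng(seed)
    if len(pos) <= len(neg):
        keep_min, maj = pos, neg
    else:
        keep_min, maj = neg, pos
    keep_maj = rng.choice(maj, size=len(keep_min), replace=False)
    idx = np.sort(np.concatenate([keep_min, keep_maj]))
    return ws.subset(idx)


class Normalizer:
    """Per-channel z-score normalization fit on training windows only."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, ws: WindowSet) -> "Normalizer":
        x = ws.windows  # (n, c, t)
        self.mean_ = x.mean(axis=(0, 2))
        sd = x.std(axis=(0, 2))
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, ws: WindowSet) -> WindowSet:
        if self.mean_ is None:
            raise ValidationError("Normalizer used before fit")
        x = (ws.windows - self.mean_[None, :, None]) / self.sd_[None, :, None]
        return WindowSet(windows=x, labels=ws.labels, sources=list(ws.sources), window_s=ws.window_s)

    def fit_transform(self, ws: WindowSet) -> WindowSet:
        return self.fit(ws).transform(ws)
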