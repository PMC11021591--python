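"""Minimal European Data Format (EDF) codec.

Supports the subset of EDF needed for scalp-EEG pipelines: 16-bit signed
samples, one physical dimension per signal, identical sampling rate across
channels, integer-second record duration. Annotations (EDF+) are *not*
handled here; seizure intervals travel in a plain-text sidecar file (see
:mod:`amda.eeg_io`).
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

__all__ = ["EdfError", "EdfSignal", "read_edf_file", "write_edf_file"]

_DIG_MIN = -32768
_DIG_MAX = 32767


class EdfError(ValueError):
    """Raised when a file cannot be parsed as (supported) EDF."""


@dataclass
class EdfSignal:
    """One channel as stored on disk."""

    label: str
    fs: float
    data: np.ndarray  # physical units (float64)


def _field(raw: bytes, start: int, length: int) -> str:
    return raw[start : start + length].decode("ascii", errors="replace").strip()


def _numeric(raw: bytes, start: int, length: int, what: str) -> float:
    text = _field(raw, start, length)
    try:
        return float(text)
    except ValueError as exc:  # pragma: no cover - defensive
        raise EdfError(f"non-numeric EDF header field {what!r}: {text!r}") from exc


def read_edf_file(path) -> list[EdfSignal]:
    """Read an EDF file into per-channel physical-unit arrays.

    Raises
    ------
    EdfError
        If the file is truncated, not EDF, or uses unsupported features.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 256:
        raise EdfError(f"{path}: file shorter than the 256-byte EDF header")
    version = _field(raw, 0, 8)
    if version != "0":
        raise EdfError(f"{path}: unsupported EDF version field {version!r}")
    header_bytes = int(_numeric(raw, 184, 8, "header bytes"))
    n_records = int(_numeric(raw, 236, 8, "number of records"))
    record_dur = _numeric(raw, 244, 8, "record duration")
    ns = int(_numeric(raw, 252, 4, "signal count"))
    if ns < 1:
        raise EdfError(f"{path}: no signals")
    if len(raw) < header_bytes:
        raise EdfError(f"{path}: truncated signal header")
    sig = raw[256:header_bytes]

    # offsets within per-signal header block, in bytes-per-signal units:
    # label 16, transducer 80, dim 8, pmin 8, pmax 8, dmin 8, dmax 8,
    # prefilter 80, samples-per-record 8, reserved 32
    base = 0
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    offsets = {}
    for name, w in zip(
        ["label", "transducer", "dim", "pmin", "pmax", "dmin", "dmax", "prefilter", "spr", "reserved"],
        widths,
    ):
        offsets[name] = (base, w)
        base += w * ns

    def read_col(name: str, i: int) -> str:
        start, w = offsets[name]
        return sig[start + w * i : start + w * (i + 1)].decode("ascii", errors="replace").strip()

    labels = [read_col("label", i) for i in range(ns)]
    pmin = np.array([float(read_col("pmin", i)) for i in range(ns)])
    pmax = np.array([float(read_col("pmax", i)) for i in range(ns)])
    dmin = np.array([float(read_col("dmin", i)) for i in range(ns)])
    dmax = np.array([float(read_col("dmax", i)) for i in range(ns)])
    spr = np.array([int(read_col("spr", i)) for i in range(ns)])
    if np.any(dmax <= dmin):
        raise EdfError(f"{path}: digital max <= digital min")
    if record_dur <= 0:
        raise EdfError(f"{path}: non-positive record duration")

    rec_len = int(spr.sum()) * 2
    body = raw[header_bytes:]
    if n_records < 0:  # "unknown" marker -1; infer from size
        n_records = len(body) // rec_len
    if len(body) < n_records * rec_len:
        raise EdfError(f"{path}: data section truncated")
    flat = np.frombuffer(body[: n_records * rec_len], dtype="<i2")
    flat = flat.reshape(n_records, int(spr.sum()))
    gains = (pmax - pmin) / (dmax - dmin)
    signals: list[EdfSignal] = []
    bounds = np.concatenate([[0], np.cumsum(spr)])
    for i in range(ns):
        dig = flat[:, bounds[i] : bounds[i + 1]].reshape(-1).astype(np.float64)
        phys = gains[i] * (dig - dmin[i]) + pmin[i]
        signals.append(EdfSignal(label=labels[i], fs=spr[i] / record_dur, data=phys))
    return signals


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf_file(
    path,
    signal: np.ndarray,
    fs: float,
    channel_names: list[str],
    patient_id: str = "X",
    physical_dim: str = "uV",
) -> None:
    """Write a [channels x samples] float array as 16-bit EDF.

    Uses 1-second data records, so ``fs`` must be a positive integer and
    trailing samples beyond a whole second are dropped (with the same
    truncation applied to every channel).
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 2:
        raise EdfError("signal must be [channels x samples]")
    n_ch, n_samp = signal.shape
    if len(channel_names) != n_ch:
        raise EdfError("channel_names length must match channel count")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise EdfError("writer supports positive integer sampling rates only")
    fs_i = int(round(fs))
    n_records = n_samp // fs_i
    if n_records == 0:
        raise EdfError("signal shorter than one 1-second data record")
    signal = signal[:, : n_records * fs_i]

    # per-channel physical range; symmetric so 0 uV maps to digital 0
    span = np.maximum(np.abs(signal).max(axis=1), 1e-6)
    pmin, pmax = -span, span
    gains = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    dig = np.rint((signal - pmin[:, None]) / gains[:, None]) + _DIG_MIN
    dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")

    header_bytes = 256 + 256 * n_ch
    now = _dt.datetime(2000, 1, 1)
    head = b"".join(
        [
            _pad("0", 8),
            _pad(patient_id, 80),
            _pad("amda synthetic recording", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(header_bytes), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(n_ch), 4),
        ]
    )
    cols = [
        b"".join(_pad(name, 16) for name in channel_names),
        b"".join(_pad("", 80) for _ in range(n_ch)),
        b"".join(_pad(physical_dim, 8) for _ in range(n_ch)),
        b"".join(_pad(f"{pmin[i]:.6g}"[:8], 8) for i in range(n_ch)),
        b"".join(_pad(f"{pmax[i]:.6g}"[:8], 8) for i in range(n_ch)),
        b"".join(_pad(str(_DIG_MIN), 8) for _ in range(n_ch)),
        b"".join(_pad(str(_DIG_MAX), 8) for _ in range(n_ch)),
        b"".join(_pad("", 80) for _ in range(n_ch)),
        b"".join(_pad(str(fs_i), 8) for _ in range(n_ch)),
        b"".join(_pad("", 32) for _ in range(n_ch)),
    ]
    # records: for each second, each channel's fs_i samples contiguously
    per_rec = dig.reshape(n_ch, n_records, fs_i)  # ch, rec, sample
    body = per_rec.transpose(1, 0, 2).tobytes()
    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(b"".join(cols))
        fh.write(body)
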