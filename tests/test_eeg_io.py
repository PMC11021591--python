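import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amda.edf import write_edf_file
from amda.eeg_io import (
    Normalizer,
    Recording,
    ValidationError,
    balance,
    parse_chbmit_summary,
    read_annotations,
    read_edf,
    segment,
    split,
    write_annotations,
)


def brute_force_label(rec: Recording, start_idx: int, stop_idx: int, rule: float) -> int:
    """Independent per-sample labeler: sample k is ictal iff any interval
    contains time k/fs."""
    count = 0
    for k in range(start_idx, stop_idx):
        t = k / rec.fs
        if any(s <= t < e for s, e in rec.seizures):
            count += 1
    return int(count / (stop_idx - start_idx) >= rule)


# ---------------------------------------------------------------------- I/O


def test_read_edf_roundtrip_no_seizures(tmp_path, make_recording):
    rec = make_recording(duration_s=10.0, fs=32.0, n_channels=2)
    path = tmp_path / "r.edf"
    write_edf_file(path, rec.signal, rec.fs, rec.channel_names)
    out = read_edf(path)
    assert out.n_samples == 10 * 32
    assert out.seizures == []
    assert out.n_channels == 2


def test_annotation_parse_identity(tmp_path):
    path = tmp_path / "ann.txt"
    write_annotations(path, [(100.0, 130.0)])
    assert read_annotations(path) == [(100.0, 130.0)]


def test_annotation_beyond_duration_rejected(tmp_path, make_recording):
    rec = make_recording(duration_s=300.0, fs=16.0)
    edf = tmp_path / "r.edf"
    ann = tmp_path / "r.txt"
    write_edf_file(edf, rec.signal, rec.fs, rec.channel_names)
    ann.write_text("290 310\n")
    with pytest.raises(ValidationError):
        read_edf(edf, ann)


def test_required_channels_select_and_reorder(tmp_path, make_recording):
    rec = make_recording(n_channels=3, duration_s=5.0, fs=16.0)
    path = tmp_path / "r.edf"
    write_edf_file(path, rec.signal, rec.fs, ["FP1", "FP2", "CZ"])
    out = read_edf(path, required_channels=["cz", "fp1"])
    assert out.channel_names == ["CZ", "FP1"]
    with pytest.raises(ValidationError, match="missing required channels"):
        read_edf(path, required_channels=["FP1", "O2"])


def test_chbmit_summary_adapter(tmp_path):
    text = """\
File Name: chb01_03.edf
Number of Seizures in File: 1
Seizure Start Time: 2996 seconds
Seizure End Time: 3036 seconds

File Name: chb01_04.edf
Number of Seizures in File: 0
"""
    path = tmp_path / "chb01-summary.txt"
    path.write_text(text)
    parsed = parse_chbmit_summary(path)
    assert parsed == {"chb01_03.edf": [(2996.0, 3036.0)], "chb01_04.edf": []}


# ------------------------------------------------------------------ segment


def test_segment_counts_hour_recording(make_recording):
    rec = make_recording(duration_s=3600.0, fs=64.0, n_channels=1)
    ws = segment(rec, window_s=30.0)
    assert len(ws) == 120
    assert ws.windows.shape == (120, 1, 30 * 64)


def test_segment_label_rule_boundary(make_recording):
    rec = make_recording(duration_s=300.0, fs=32.0, seizures=[(100.0, 130.0)])
    ws = segment(rec, window_s=30.0, label_rule=0.5)
    starts = {src[1]: lab for src, lab in zip(ws.sources, ws.labels)}
    assert starts[90.0] == 1  # 20/30 s inside the seizure
    assert starts[120.0] == 0  # 10/30 s inside
    assert starts[0.0] == 0


def test_segment_short_recording_warns_empty(make_recording):
    rec = make_recording(duration_s=29.0, fs=16.0)
    with pytest.warns(UserWarning):
        ws = segment(rec, window_s=30.0)
    assert len(ws) == 0


def test_segment_windows_are_exact_slices(make_recording):
    rec = make_recording(duration_s=120.0, fs=16.0)
    ws = segment(rec, window_s=30.0)
    for (_, start_s), w in zip(ws.sources, ws.windows):
        a = int(start_s * rec.fs)
        np.testing.assert_array_equal(w, rec.signal[:, a : a + w.shape[1]])


@settings(max_examples=60, deadline=None)
@given(
    duration=st.floats(min_value=1.0, max_value=2000.0),
    window=st.floats(min_value=1.0, max_value=120.0),
    overlap_frac=st.floats(min_value=0.0, max_value=0.9),
)
def test_window_count_law(duration, window, overlap_frac):
    fs = 4.0
    overlap = round(overlap_frac * window * fs) / fs  # sample-aligned
    rec = Recording(
        signal=np.zeros((1, int(round(duration * fs)))), fs=fs, channel_names=["A"],
    )
    win = int(round(window * fs))
    stride = int(round((window - overlap) * fs))
    if stride < 1:
        return
    expected = (rec.n_samples - win) // stride + 1 if rec.n_samples >= win else 0
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ws = segment(rec, window_s=window, overlap_s=overlap)
    assert len(ws) == max(expected, 0)


def test_label_equivalence_brute_force(make_recording):
    rng = np.random.default_rng(99)
    for case in range(100):
        fs = float(rng.choice([8, 16, 32]))
        duration = float(rng.uniform(60, 240))
        n_seiz = int(rng.integers(0, 4))
        seizures = []
        for _ in range(n_seiz):
            s = float(rng.uniform(0, duration - 5))
            e = float(rng.uniform(s + 1, min(duration, s + 60)))
            seizures.append((s, e))
        rec = make_recording(duration_s=duration, fs=fs, n_channels=1, seizures=seizures, seed=case)
        rule = float(rng.choice([0.25, 0.5, 0.75]))
        ws = segment(rec, window_s=15.0, label_rule=rule)
        win = int(15.0 * fs)
        for (_, start_s), label in zip(ws.sources, ws.labels):
            a = int(round(start_s * fs))
            assert label == brute_force_label(rec, a, a + win, rule)


# ------------------------------------------------------------ split/balance


def _labeled_ws(n, labels, seed=0):
    from amda.eeg_io import WindowSet

    gen = np.random.default_rng(seed)
    return WindowSet(
        windows=gen.standard_normal((n, 1, 8)),
        labels=np.asarray(labels),
        sources=[("p0", float(i)) for i in range(n)],
        window_s=1.0,
    )


def test_split_stratified_counts():
    ws = _labeled_ws(100, [0] * 50 + [1] * 50)
    tr, te = split(ws, train_frac=0.7, seed=0, stratified=True)
    assert len(tr) == 70 and len(te) == 30
    assert int(np.sum(tr.labels)) == 35 and int(np.sum(te.labels)) == 15


def test_split_deterministic_partition():
    ws = _labeled_ws(60, [0] * 30 + [1] * 30)
    tr1, te1 = split(ws, 0.7, seed=5)
    tr2, te2 = split(ws, 0.7, seed=5)
    np.testing.assert_array_equal(tr1.windows, tr2.windows)
    np.testing.assert_array_equal(te1.windows, te2.windows)
    starts = sorted([s for _, s in tr1.sources] + [s for _, s in te1.sources])
    assert starts == [float(i) for i in range(60)]  # partition: union is everything
    assert not set(s for _, s in tr1.sources) & set(s for _, s in te1.sources)


def test_split_single_class_stratified_rejected():
    ws = _labeled_ws(10, [0] * 10)
    with pytest.raises(ValidationError):
        split(ws, 0.7, seed=0, stratified=True)


def test_split_by_patient_is_patient_disjoint():
    from amda.eeg_io import WindowSet

    gen = np.random.default_rng(3)
    n = 40
    ws = WindowSet(
        windows=gen.standard_normal((n, 1, 8)),
        labels=(np.arange(n) % 2),
        sources=[(f"p{i % 5}", float(i)) for i in range(n)],
        window_s=1.0,
    )
    tr, te = split(ws, 0.6, seed=0, by_patient=True)
    assert not {p for p, _ in tr.sources} & {p for p, _ in te.sources}
    assert len(tr) + len(te) == n


def test_balance_undersample_counts():
    ws = _labeled_ws(410, [1] * 10 + [0] * 400)
    out = balance(ws, "undersample", seed=0)
    assert len(out) == 20
    assert int(np.sum(out.labels)) == 10


def test_balance_none_identity():
    ws = _labeled_ws(20, [0] * 10 + [1] * 10)
    assert balance(ws, "none") is ws


def test_balance_deterministic():
    ws = _labeled_ws(100, [1] * 5 + [0] * 95)
    a = balance(ws, "undersample", seed=11)
    b = balance(ws, "undersample", seed=11)
    np.testing.assert_array_equal(a.windows, b.windows)


def test_normalizer_train_stats_only():
    tr = _labeled_ws(50, [0] * 25 + [1] * 25, seed=1)
    te = _labeled_ws(30, [0] * 15 + [1] * 15, seed=2)
    norm = Normalizer().fit(tr)
    trn = norm.transform(tr)
    assert np.allclose(trn.windows.mean(axis=(0, 2)), 0, atol=1e-12)
    assert np.allclose(trn.windows.std(axis=(0, 2)), 1, atol=1e-12)
    ten = norm.transform(te)  # test uses *training* statistics
    expected = (te.windows - tr.windows.mean(axis=(0, 2))[None, :, None]) / tr.windows.std(
        axis=(0, 2)
    )[None, :, None]
    np.testing.assert_allclose(ten.windows, expected)
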