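"""End-to-end experiment grid: {no augmentation, 1x, 2x, 3x} arms, plus the
attention ablation and the evaluation-time noise probe.

Each (arm, seed) cell runs: generate/load -> window -> balance -> split ->
normalize (training statistics only) -> pre-train on raw -> amplify ->
train -> evaluate on the held-out fraction. Results are pooled over all
test windows; every cell is reproducible from config + seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .augmentation import AugmentationConfig, amplify
from .eeg_io import Normalizer, Recording, ValidationError, WindowSet, balance, read_edf, segment, split
from .evaluation import EvalReport, evaluate
from .model import ModelConfig, build, predict, train
from .synth import SynthConfig, add_noise, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment", "ablation", "noise_probe"]

METRICS = ("ACC", "SEN", "SPE", "AUC")


@dataclass
class ExperimentConfig:
    # data source: synthetic generator settings or a directory of EDF files
    data_kind: str = "synthetic"  # "synthetic" | "edf"
    edf_dir: str | None = None
    n_recordings: int = 10
    duration_s: float = 300.0
    n_channels: int = 18
    fs: float = 64.0
    seizure_fraction: float = 0.5
    amplitude_gain: float = 3.0
    align_s: float | None = 30.0
    # windowing / split / balance
    window_s: float = 30.0
    overlap_s: float = 0.0
    label_rule: float = 0.5
    train_frac: float = 0.7
    stratified: bool = True
    by_patient: bool = False
    balance_policy: str = "undersample"
    # augmentation
    epsilon: float = 0.1
    mixup_alpha: float = 0.2
    mix_ratio: float = 0.5
    # grid
    arms: tuple[int, ...] = (0, 1, 2, 3)
    seeds: tuple[int, ...] = (0, 1, 2)
    pretrain_epochs: int = 10
    model: ModelConfig = field(default_factory=ModelConfig)
    # probes
    noise_sd: float = 0.0
    drift_amp: float = 0.0

    def __post_init__(self) -> None:
        if not set(self.arms) <= {0, 1, 2, 3}:
            raise ValidationError("arms must be a subset of {0, 1, 2, 3}")
        if len(self.seeds) < 1:
            raise ValidationError("at least one seed is required")
        if self.data_kind not in ("synthetic", "edf"):
            raise ValidationError(f"unknown data_kind {self.data_kind!r}")
        if self.data_kind == "edf" and not self.edf_dir:
            raise ValidationError("data_kind 'edf' requires edf_dir")

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        model_raw = raw.pop("model", {})
        if "conv_channels" in model_raw:
            model_raw["conv_channels"] = tuple(model_raw["conv_channels"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("arms", "seeds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(model=ModelConfig(**model_raw), **raw)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------


def _load_recordings(cfg: ExperimentConfig, seed: int) -> list[Recording]:
    if cfg.data_kind == "edf":
        recs = []
        for name in sorted(os.listdir(cfg.edf_dir)):
            if not name.lower().endswith(".edf"):
                continue
            stem = os.path.join(cfg.edf_dir, name[:-4])
            ann = None
            for suffix in (".seizures.txt", ".txt"):
                if os.path.exists(stem + suffix):
                    ann = stem + suffix
                    break
            recs.append(read_edf(os.path.join(cfg.edf_dir, name), ann, patient_id=name[:-4]))
        if not recs:
            raise ValidationError(f"no EDF files found in {cfg.edf_dir}")
        return recs
    template = SynthConfig(
        n_channels=cfg.n_channels,
        fs=cfg.fs,
        duration_s=cfg.duration_s,
        amplitude_gain=cfg.amplitude_gain,
    )
    return generate_dataset(
        cfg.n_recordings, template, seizure_fraction=cfg.seizure_fraction,
        seed=seed, align_s=cfg.align_s,
    )


def _prepare(cfg: ExperimentConfig, seed: int):
    """Window, balance, split and normalize; returns (train, test, normalizer)."""
    recs = _load_recordings(cfg, seed)
    ws = WindowSet.concatenate(
        [segment(r, cfg.window_s, cfg.overlap_s, cfg.label_rule) for r in recs]
    )
    ws = balance(ws, cfg.balance_policy, seed=seed)
    train_ws, test_ws = split(
        ws, cfg.train_frac, seed=seed, stratified=cfg.stratified, by_patient=cfg.by_patient
    )
    train_keys = set(map(tuple, train_ws.sources))
    test_keys = set(map(tuple, test_ws.sources))
    if train_keys & test_keys:
        raise AssertionError("train/test leakage: shared (patient, start) windows")
    norm = Normalizer().fit(train_ws)
    return norm.transform(train_ws), norm.transform(test_ws), norm


def _run_arm(
    cfg: ExperimentConfig, arm: int, seed: int, train_ws: WindowSet, test_ws: WindowSet,
    attention: bool | None = None,
) -> tuple[EvalReport, object]:
    mcfg = replace(
        cfg.model,
        seed=seed,
        attention=cfg.model.attention if attention is None else attention,
    )
    n_ch = train_ws.windows.shape[1]
    n_samp = train_ws.windows.shape[2]
    if arm == 0:
        model = build(mcfg, n_ch, n_samp)
        train(model, train_ws, mcfg)
    else:
        pre_cfg = replace(mcfg, epochs=cfg.pretrain_epochs)
        pre_model = build(pre_cfg, n_ch, n_samp)
        train(pre_model, train_ws, pre_cfg)
        aug_cfg = AugmentationConfig(
            epsilon=cfg.epsilon, multiplier=arm, mixup_alpha=cfg.mixup_alpha,
            mix_ratio=cfg.mix_ratio, seed=seed,
        )
        augmented = amplify(train_ws, pre_model, aug_cfg)
        model = build(mcfg, n_ch, n_samp)
        train(model, augmented, mcfg)
    probs, _ = predict(model, test_ws)
    return evaluate(test_ws.labels, probs), model


def _summarize(rows: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    agg = rows.groupby(by)[list(METRICS)].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


def run_experiment(cfg: ExperimentConfig, out_dir=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every (arm, seed) cell; returns (per-cell rows, per-arm summary).

    A failing arm is logged and skipped; the remaining arms still run.
    """
    rows = []
    for seed in cfg.seeds:
        train_ws, test_ws, _ = _prepare(cfg, seed)
        for arm in cfg.arms:
            try:
                report, _ = _run_arm(cfg, arm, seed, train_ws, test_ws)
            except Exception:
                logger.exception("arm %d (seed %d) failed; continuing", arm, seed)
                continue
            rows.append({
                "arm": arm, "seed": seed,
                "ACC": report.acc, "SEN": report.sen,
                "SPE": report.spe, "AUC": report.auc,
                "TP": report.tp, "TN": report.tn, "FP": report.fp, "FN": report.fn,
            })
    results = pd.DataFrame(rows)
    summary = _summarize(results, ["arm"]) if len(results) else pd.DataFrame()
    if out_dir is not None:
        _write_outputs(cfg, results, summary, out_dir)
    return results, summary


def _write_outputs(cfg, results, summary, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    results.to_csv(os.path.join(out_dir, "results.csv"), index=False)
    summary.to_csv(os.path.join(out_dir, "summary.csv"), index=False)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seeds": list(cfg.seeds),
        "versions": {"amda": __version__, "numpy": np.__version__, "pandas": pd.__version__},
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)


def ablation(cfg: ExperimentConfig, out_dir=None) -> pd.DataFrame:
    """Matched arms with and without the attention layer; paired deltas."""
    rows = []
    for seed in cfg.seeds:
        train_ws, test_ws, _ = _prepare(cfg, seed)
        for arm in cfg.arms:
            for attention in (True, False):
                report, _ = _run_arm(cfg, arm, seed, train_ws, test_ws, attention=attention)
                rows.append({
                    "arm": arm, "seed": seed, "attention": attention,
                    "ACC": report.acc, "SEN": report.sen,
                    "SPE": report.spe, "AUC": report.auc,
                })
    df = pd.DataFrame(rows)
    paired = []
    for arm in cfg.arms:
        sub = df[df["arm"] == arm]
        with_att = sub[sub["attention"]][list(METRICS)].mean()
        without = sub[~sub["attention"]][list(METRICS)].mean()
        row = {"arm": arm}
        for m in METRICS:
            row[f"{m}_with"] = with_att[m]
            row[f"{m}_without"] = without[m]
            row[f"{m}_delta"] = with_att[m] - without[m]
        paired.append(row)
    paired_df = pd.DataFrame(paired)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        df.to_csv(os.path.join(out_dir, "ablation_cells.csv"), index=False)
        paired_df.to_csv(os.path.join(out_dir, "ablation_paired.csv"), index=False)
    return paired_df


def noise_probe(cfg: ExperimentConfig, out_dir=None) -> pd.DataFrame:
    """Evaluate trained models on clean vs noise-injected test windows.

    Noise (broadband + slow drift) is added to the raw test windows, which
    are then re-normalized with the training statistics; test indices are
    identical between the two conditions.
    """
    arm = cfg.arms[0]
    rows = []
    for seed in cfg.seeds:
        recs = _load_recordings(cfg, seed)
        ws = WindowSet.concatenate(
            [segment(r, cfg.window_s, cfg.overlap_s, cfg.label_rule) for r in recs]
        )
        ws = balance(ws, cfg.balance_policy, seed=seed)
        train_raw, test_raw = split(
            ws, cfg.train_frac, seed=seed, stratified=cfg.stratified, by_patient=cfg.by_patient
        )
        norm = Normalizer().fit(train_raw)
        train_ws = norm.transform(train_raw)
        test_ws = norm.transform(test_raw)
        report_clean, model = _run_arm(cfg, arm, seed, train_ws, test_ws)
        noisy_windows = add_noise(
            test_raw.windows, cfg.noise_sd, drift_amp=cfg.drift_amp, fs=cfg.fs, seed=seed,
        )
        noisy_raw = WindowSet(
            windows=noisy_windows, labels=test_raw.labels,
            sources=list(test_raw.sources), window_s=test_raw.window_s,
        )
        noisy_ws = norm.transform(noisy_raw)
        probs, _ = predict(model, noisy_ws)
        report_noisy = evaluate(noisy_ws.labels, probs)
        for condition, rep in (("clean", report_clean), ("noisy", report_noisy)):
            rows.append({
                "arm": arm, "seed": seed, "condition": condition,
                "ACC": rep.acc, "SEN": rep.sen, "SPE": rep.spe, "AUC": rep.auc,
            })
    df = pd.DataFrame(rows)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        df.to_csv(os.path.join(out_dir, "noise_probe.csv"), index=False)
    return df
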