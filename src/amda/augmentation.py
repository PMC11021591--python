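"""Adversarial + mixup training-set amplification.

Adversarial samples solve ``argmax J(theta, x_adv, y) s.t. ||x_adv - x||_inf
<= eps`` with the single-step sign-gradient solution ``x_adv = x + eps *
sign(dJ/dx)`` (a projected multi-step variant is available). Mixup samples
are convex combinations of window pairs and their labels with coefficient
``lambda ~ Beta(alpha, alpha)``. ``amplify`` emits the original training set
plus ``n`` times its size in generated samples.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .eeg_io import ValidationError, WindowSet

__all__ = [
    "AugmentationConfig",
    "AugmentedSet",
    "NumericError",
    "adversarial_perturb",
    "mixup",
    "amplify",
]


class NumericError(ArithmeticError):
    pass


@dataclass
class AugmentationConfig:
    """epsilon is an L-inf budget in normalized (per-channel SD) units;
    multiplier n in {0,1,2,3} scales the generated-sample count; mix_ratio
    is the fraction of generated samples produced by mixup (the rest are
    adversarial)."""

    epsilon: float = 0.1
    multiplier: int = 1
    mixup_alpha: float = 0.2
    mix_ratio: float = 0.5
    adversarial_steps: int = 1  # >1 => projected iterative ascent
    seed: int = 0

    def validate(self) -> None:
        if self.epsilon < 0:
            raise ValidationError("epsilon must be >= 0")
        if self.multiplier < 0:
            raise ValidationError("multiplier must be >= 0")
        if self.mixup_alpha <= 0:
            raise ValidationError("mixup_alpha must be > 0")
        if not 0 <= self.mix_ratio <= 1:
            raise ValidationError("mix_ratio must be in [0, 1]")
        if self.adversarial_steps < 1:
            raise ValidationError("adversarial_steps must be >= 1")


@dataclass
class AugmentedSet:
    """Original + generated windows with per-window provenance.

    ``origin`` holds 'original' | 'adversarial' | 'mixup'; ``provenance``
    has one ``(src_i, src_j, lam)`` triple per window (j = -1 and lam = nan
    for non-mixup windows).
    """

    windows: np.ndarray
    labels: np.ndarray  # soft labels in [0, 1]
    origin: np.ndarray  # array of strings
    provenance: list[tuple[int, int, float]]
    window_s: float

    def __len__(self) -> int:
        return len(self.windows)

    def save(self, windows_path, provenance_path) -> None:
        """Portable array container + tabular sidecar."""
        np.savez(windows_path, windows=self.windows, labels=self.labels)
        with open(provenance_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["origin", "src_i", "src_j", "lam", "label"])
            for origin, (i, j, lam), label in zip(self.origin, self.provenance, self.labels):
                writer.writerow([origin, i, j, f"{lam:.9g}", f"{float(label):.9g}"])


def adversarial_perturb(model, x: np.ndarray, y, eps: float, steps: int = 1) -> np.ndarray:
    """Loss-maximizing perturbation within an L-inf ball of radius eps.

    ``model`` needs only an ``input_gradient(x, y)`` method. One step is
    the sign-gradient solution; with ``steps > 1`` the ascent uses step
    size ``eps / steps`` with projection back onto the ball, so
    ``max|x_adv - x| <= eps`` holds exactly either way.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if eps == 0:
        return x.copy()
    x_adv = x.copy()
    step = eps / steps
    for _ in range(steps):
        g = model.input_gradient(x_adv, y)
        if not np.all(np.isfinite(g)):
            bad = int(np.sum(~np.isfinite(g)))
            raise NumericError(f"non-finite input gradient ({bad} entries)")
        x_adv = x_adv + step * np.sign(g)
        x_adv = np.clip(x_adv, x - eps, x + eps)
    return x_adv


def mixup(x_i: np.ndarray, y_i, x_j: np.ndarray, y_j, lam: float) -> tuple[np.ndarray, float]:
    """Convex combination of two windows and their labels."""
    x_i = np.asarray(x_i, dtype=np.float64)
    x_j = np.asarray(x_j, dtype=np.float64)
    if x_i.shape != x_j.shape:
        raise ValidationError(f"shape mismatch: {x_i.shape} vs {x_j.shape}")
    if not 0 <= lam <= 1:
        raise ValidationError("lam must be in [0, 1]")
    return lam * x_i + (1 - lam) * x_j, lam * float(y_i) + (1 - lam) * float(y_j)


def amplify(train: WindowSet, model, cfg: AugmentationConfig) -> AugmentedSet:
    """Amplify a training set to ``(1 + n)`` times its size.

    Emits the original windows first, then the generated ones:
    adversarial sources cycle through the training set in order; mixup
    draws its primary index from the same cycle, its partner uniformly,
    and its coefficient from Beta(alpha, alpha). Fully deterministic under
    ``cfg.seed``. Requires a pre-trained model whenever n > 0 (the
    classifier must first be fit on the raw training data).
    """
    cfg.validate()
    m = len(train)
    if m == 0:
        raise ValidationError("training set is empty")
    base_origin = ["original"] * m
    base_prov = [(i, -1, float("nan")) for i in range(m)]
    if cfg.multiplier == 0:
        return AugmentedSet(
            windows=train.windows.copy(),
            labels=np.asarray(train.labels, dtype=np.float64).copy(),
            origin=np.array(base_origin),
            provenance=base_prov,
            window_s=train.window_s,
        )
    if model is None or not getattr(model, "trained", False):
        raise ValidationError("amplify with multiplier > 0 requires a pre-trained model")

    rng = np.random.default_rng(cfg.seed)
    n_gen = cfg.multiplier * m
    n_mix = int(round(cfg.mix_ratio * n_gen))
    n_adv = n_gen - n_mix
    x = np.asarray(train.windows, dtype=np.float64)
    y = np.asarray(train.labels, dtype=np.float64)

    cycle = np.arange(n_gen) % m  # sources cycled through train in order
    adv_src = cycle[:n_adv]
    mix_src = cycle[n_adv:]

    gen_windows = []
    gen_labels = []
    origin = list(base_origin)
    prov = list(base_prov)

    batch = 256
    for start in range(0, n_adv, batch):
        idx = adv_src[start : start + batch]
        x_adv = adversarial_perturb(model, x[idx], y[idx], cfg.epsilon, steps=cfg.adversarial_steps)
        gen_windows.append(x_adv)
        gen_labels.append(y[idx])  # adversarial windows keep the source label
        origin.extend(["adversarial"] * len(idx))
        prov.extend((int(i), -1, float("nan")) for i in idx)

    if n_mix:
        partners = rng.integers(0, m, size=n_mix)
        lams = rng.beta(cfg.mixup_alpha, cfg.mixup_alpha, size=n_mix)
        mixed = lams[:, None, None] * x[mix_src] + (1 - lams[:, None, None]) * x[partners]
        gen_windows.append(mixed)
        gen_labels.append(lams * y[mix_src] + (1 - lams) * y[partners])
        origin.extend(["mixup"] * n_mix)
        prov.extend(
            (int(i), int(j), float(l)) for i, j, l in zip(mix_src, partners, lams)
        )

    windows = np.concatenate([x] + gen_windows) if gen_windows else x.copy()
    labels = np.concatenate([y] + gen_labels) if gen_labels else y.copy()
    return AugmentedSet(
        windows=windows,
        labels=labels,
        origin=np.array(origin),
        provenance=prov,
        window_s=train.window_s,
    )
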