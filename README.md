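# amda

Seizure detection in multichannel EEG with adversarial + mixup data
augmentation (AMDA) and an attention-augmented 1D CNN-GRU classifier —
implemented in pure NumPy (hand-derived backpropagation, no deep-learning
framework required).

## What it does

1. **eeg_io** — reads EDF recordings plus plain-text seizure annotations
   (one `start_s end_s` pair per line; a CHB-MIT summary-file adapter is
   included), segments them into fixed-length labeled windows (default
   30 s, non-overlapping, window is ictal iff ≥ 50 % of its samples fall in
   an annotated interval), and provides stratified or patient-disjoint
   70/30 splits, undersample balancing, and per-channel z-score
   normalization fit on training windows only.
2. **synth** — seeded synthetic EEG-like recordings (band-limited
   background + 1/f noise; seizures = 3 Hz rhythm with sharp transients)
   with EDF + annotation writers, so the whole pipeline runs with no
   download.
3. **augmentation** — AMDA: adversarial samples via the sign-gradient
   solution of `argmax J(θ, x̄, y) s.t. ‖x̄ − x‖∞ ≤ ε` (optional multi-step
   projected ascent), mixup convex combinations with `λ ~ Beta(α, α)`, and
   `amplify`, which grows a training set to `(1 + n)×` its size with full
   per-window provenance.
4. **model** — the classifier: conv(kernel 3, same padding) + max-pool
   blocks → scaled dot-product self-attention (`softmax(QKᵀ/√d)·V`) →
   GRU(128) → dropout(0.5) → sigmoid head; binary cross-entropy with soft
   labels; Adam (lr 0.001, batch 256, 50 epochs by default); exposes
   `input_gradient` for the adversarial step and an attention-bypass
   ablation flag.
5. **evaluation** — confusion counts, ACC/SEN/SPE, tie-grouped ROC and
   trapezoid AUC (validated against a Mann–Whitney pairwise oracle).
6. **experiment** — the {0×, 1×, 2×, 3×} augmentation grid with mean ± sd
   over seeds, the attention ablation, and a clean-vs-noisy robustness
   probe; every run is reproducible from its `manifest.json`.

## CLI

```sh
# generate a synthetic EDF dataset
amda synth --n 10 --duration 300 --seizure-fraction 0.1 --seed 7 --out data/

# train one model (n = augmentation multiplier)
amda train --config experiment.yaml --n 1 --epsilon 0.1 --out run/

# full experiment grid / ablation / noise probe
amda-experiment run --config experiment.yaml --out runs/grid
amda-experiment ablation --config experiment.yaml
amda-experiment noise --config experiment.yaml
```

`experiment.yaml` holds one flat config for all stages, e.g.:

```yaml
n_recordings: 10
duration_s: 300.0
n_channels: 18
fs: 32.0
seizure_fraction: 0.5
arms: [0, 1, 2, 3]
seeds: [0, 1, 2]
epsilon: 0.1
model:
  epochs: 15
  batch_size: 16
```

Use `data_kind: edf` + `edf_dir: path/` to run on real EDF recordings with
`<name>.seizures.txt` annotation sidecars instead of synthetic data.

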