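# alarmsieve

Discriminating true from false ICU arrhythmia alarms in multi-channel
bedside-monitor waveforms (2 ECG leads plus pulsatile channels, 250 Hz,
alarm raised 5 minutes in). The classifier is a Siamese contrastive
framework:

- a **1-D CNN signal encoder** with four parallel blocks (kernel sizes
  50/100/200/400, two conv→batch-norm→ReLU stages of 64 filters at stride 5
  each, global max pooling) applied to the 10 s window preceding the alarm;
- a **pair-wise discriminative constraint**: the same encoder (strict weight
  sharing) also embeds a randomly sampled pre-alarm *baseline* window of the
  same record; features of the two windows are pulled together for false
  alarms and pushed apart for true alarms via `-log σ(±f_A·f_R)`;
- an **alarm-type embedding** (one-hot × learned matrix) and a **rule-based
  embedding** (a scalar rule verdict R ∈ [0,1] scaling a learned vector),
  concatenated with the encoder output into a sigmoid classifier;
- training minimizes `L = weighted_BCE + w·C` with Adam, class weight 1.5 on
  true alarms, constraint weight 1.5, L2 5e-4, dropout 0.8 before each block.

Evaluation uses the Challenge score `(TP+TN)/(TP+TN+FP+5·FN)` plus
TPR/TNR/ACC, stratified five-fold cross-validation, and a four-row ablation
grid (basic / +constraint / +rule / full).

The neural network is implemented in NumPy with hand-written gradients (no
GPU/torch dependency); WFDB format-16 records are read and written natively.

## Layout

| Module | Contents |
| --- | --- |
| `alarmsieve.data_io` | WFDB + fixture I/O, manifests, 0–1 pre-processing, Siamese segment-pair extraction, stratified fold splitting |
| `alarmsieve.synthetic_data` | seeded generator of labeled records with per-type rhythm signatures and artifact-driven false alarms, plus ground truth |
| `alarmsieve.rule_scorer` | beat detection (band-pass → square → integrate → adaptive peaks) and per-type decision rules producing R; pluggable |
| `alarmsieve.nn` | conv1d / batch-norm / ReLU / dropout / global max-pool primitives with manual gradients; Adam |
| `alarmsieve.model` | encoder + embedding layers + classifier, Siamese forward, checkpoints |
| `alarmsieve.losses` | discriminative constraints, weighted BCE, combined loss (+ gradient forms) |
| `alarmsieve.train_eval` | training loop, prediction, metrics, cross-validation, ablation |
| `alarmsieve.config` / `alarmsieve.cli` | YAML configs, run manifests, `alarmsieve` command |

## CLI

```sh
# generate a labeled synthetic dataset (fixtures + manifest.csv; --wfdb for WFDB pairs)
alarmsieve simulate --n 100 --seed 1 --out-dir data/

# train / cross-validate / ablate on a dataset directory
alarmsieve train  --data-dir data/ --out-dir runs/t0 --seed 0 --config cfg.yaml
alarmsieve cv     --data-dir data/ --out-dir runs/cv --seed 0
alarmsieve ablate --data-dir data/ --out-dir runs/ab --seed 0

# score a prediction CSV against ground truth
alarmsieve score --pred preds.csv --truth truth.csv
```

`--rule-scorer` selects the rule branch input: `reference` (built-in
beat-rule scorer), `constant:<v>`, or `plugin:<path>` (a Python file
exposing `rule_score(record) -> float`). Config files are YAML with
`train:`, `model:`, `synthetic:` and `paths:` sections; omitted keys use the
reference defaults (batch 256, lr 0.001, w 1.5, dropout 0.8, ...), unknown
keys are rejected. Every artifact-producing command writes a
`run_manifest.json` (config snapshot, seed, input digests, outputs).

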