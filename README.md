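# caehar

Continuous-autoencoder deep belief networks for wearable-sensor human
activity recognition, with a fully synthetic data path so every pipeline
stage can be exercised and tested offline.

The package implements:

- **nn_core** — a zero-centred sigmoid activation `k·(1/(1+e^(−c·a)) − 0.5)`
  with additive per-unit Gaussian stochastic noise on the pre-activation,
  single-hidden-layer continuous autoencoders (CAE), squared-error +
  weight-decay losses, and exact backpropagated gradients (verified against
  central finite differences).
- **optim** — per-sample SGD and its fast variant (FSGD): training breaks
  once the monitored epoch loss has stayed at or below a threshold ε for K
  consecutive epochs. Both share one code path, so trajectories are
  bit-identical up to the break epoch.
- **tffe** — time/frequency-domain feature extraction: per channel, mean,
  mean absolute deviation, skewness, cyclic inter-axis correlation, the
  top-5 FFT magnitudes and top-5 cepstrum values; a 125×45 segment yields
  14×45 = 630 features.
- **pca_reduce** — PCA on the pooled 45-channel axis; keeping the top 3
  components reduces 630 features to 14×3 = 42.
- **dbn** — a deep belief network built from two greedily pretrained CAEs
  (42→10→42 and 42→8→42) plus a backprop output layer onto 19 one-of-N
  class units, fine-tuned end-to-end with momentum, dropout, and the same
  early-break rule.
- **synth** — generators for a swiss-roll point cloud (normalised to
  [0, 1]) and a multi-sensor activity dataset (19 activities × 8 subjects ×
  60 segments of 125 samples × 45 channels at 25 Hz, clamped to ±5 g,
  ±1200 °/s, ±75 μT), plus a plain-text `a<ii>/p<j>/s<kk>.txt` on-disk
  layout with bit-exact round-tripping.
- **evalkit** — stratified K-fold planning, confusion matrices,
  sensor/position channel subsetting, and the end-to-end
  TFFE → PCA → DBN evaluation driver (PCA and classifier fit on training
  folds only).
- **cli_io** — the `caehar` command-line interface, YAML run configs,
  feature-table/history/checkpoint I/O.

## CLI

```sh
# synthetic data
caehar simulate --kind har --seed 0 --out data/        # segment tree
caehar simulate --kind swissroll --seed 0 --out roll/  # point cloud

# feature pipeline
caehar extract --data data/ --out features.tsv         # 5625 -> 630
caehar reduce --features features.tsv --out reduced.tsv  # 630 -> 42

# classifier
caehar train --features features.tsv --seed 0 --out model.npz
caehar predict --model model.npz --features features.tsv --out pred.tsv

# 6-fold evaluation on a scaled-down simulated dataset
caehar evaluate --simulate --segments-per-pair 10 --k 6 --seed 0 --out eval/

# swiss-roll reconstruction experiment with the FSGD early break
caehar swissroll-demo --seed 0 --out demo/
```

`caehar evaluate` writes an aggregate confusion matrix (`confusion.csv`)
and a `summary.txt` with per-fold and mean accuracies. Runs are
deterministic given `--seed`; all stage seeds derive from it.

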