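# semgnet

Surface electromyography (sEMG) measured by a forearm electrode cuff carries
enough information to decode which hand gesture its wearer is performing —
the basis of non-invasive prosthetic-hand control. `semgnet` is a desk-scale,
fully seeded implementation of a multi-stream attention pipeline for
52-gesture classification from a 16-channel, 1000 Hz cuff with a fused
3-axis accelerometer (ACC):

1. **Denoising** — a narrow IIR notch removes 50 Hz power-line interference
   and a 3rd-order Butterworth high-pass (cutoff 20 Hz, 18 dB/octave)
   removes baseline drift and motion artifact, per
   `|H(jΩ)|² = 1 / (1 + ε² (Ω_c/Ω)^{2N})`.
2. **Redundant-channel pruning** — each electrode is scored by the variance,
   across gesture classes, of its rest-corrected RMS activation; channels
   whose activity barely modulates with gestures are graded most redundant,
   the grading is repeated over 8 held-in folds, and the 10 highest-weight
   channels are removed (6 of 16 retained).
3. **Window features** — classic per-window descriptors: integrated EMG
   `IEMG = Σ|x_i|`, second-moment amplitude `VAR = (1/(N−1)) Σ x_i²`, median
   frequency MDF (the bin splitting spectral power in half), and the
   low/high frequency-band power ratio FR.
4. **1-D convolutional block attention (CBAM)** — feature-channel attention
   `M_C = σ(W₁ρ(W₀ F̄) + W₁ρ(W₀ F̂))` from time-pooled statistics, temporal
   attention `M_T = σ(f₃ₓ₁([F̄ᵀ; F̂ᵀ]))` from channel-pooled statistics,
   applied sequentially: `F′ = M_C ⊗ F`, `F″ = M_T ⊗ F′`.
5. **Multi-stream CNN + GRU classifier** — one independent branch per
   retained electrode (Conv1D → batch norm → ReLU → CBAM → GRU), one more
   branch for the accelerometer, concatenated into a dropout-regularized
   fully-connected softmax head: `p(m|g) = exp(g_m)/Σ_j exp(g_j)`,
   decision `m₀ = argmax_m p(m|g)`.

No recorded data ship with the package; a seeded generator
(`semgnet.simulate`) produces labeled recordings with the statistical
structure the method assumes (band-limited amplitude-modulated muscle noise,
50 Hz interference, baseline drift, rest/action alternation, planted
redundant channels), so every stage is testable end to end. Training runs on
a small pure-numpy reverse-mode autodiff engine bundled with the package —
no deep-learning framework required.

## Worked example

```bash
# 1. generate the easy 5-class synthetic dataset (9 repetitions per class,
#    8 train / 1 test)
semgnet simulate --out data --seed 0

# 2. train the default small model for 3 epochs
semgnet train --data data --seed 0 --epochs 3 --out run

# 3. evaluate the checkpoint
semgnet eval --checkpoint run/checkpoint.npz --data data --out eval
```

The train step prints the held-out accuracy; with the commands above it
prints

```
test accuracy: 1.000
```

meaning every one of the 95 held-out 200 ms decision windows (19 per class,
all from the repetition never seen in training) was assigned the correct
gesture — the easy spec's activation patterns are deliberately
well-separated. `run/` contains
the checkpoint, the per-epoch loss/accuracy history, the 5×5 confusion
matrix (rows = actual class, columns = predicted) and the resolved run
configuration.

Channel pruning on 16-channel recordings whose default simulator spec
plants electrodes {2,3,4,5,6,10,11,12,13,14} as non-modulating:

```bash
printf 'n_classes: 6\naction_s: 1.0\nrest_s: 0.5\nreps: 9\n' > spec16.yaml
semgnet simulate --spec spec16.yaml --out data16 --seed 0
semgnet rank-channels --data data16/train --folds 8 --remove 10 --seed 0 --out rank.csv
# removed channels: [2, 3, 4, 5, 6, 10, 11, 12, 13, 14]
```

The same API is available as a library:

```python
from semgnet import SimSpec, simulate_dataset, ModelConfig, build_model, train_model
from semgnet.pipeline import make_window_dataset

train_recs, test_recs = simulate_dataset(SimSpec.easy(seed=0))
train, test, stats = make_window_dataset(train_recs, test_recs)
model = build_model(ModelConfig(n_semg_streams=6, n_classes=5, window_samples=200))
history = train_model(model, train.x_semg, train.y, train.x_acc)
```

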