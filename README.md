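# kinetraits

Explainable multimodal prediction of human-centered traits from three
behavioral channels:

- **kinemes** — elementary head-motion units learned from pitch/yaw/roll
  Euler-angle time series (NMF basis + Gaussian-mixture clustering of the
  coefficient vectors; new windows are assigned by non-negative least-squares
  projection and maximum posterior);
- **facial action units** — per-window binary "dominant AU" vectors
  (window mean strictly above the per-video channel mean);
- **speech** — per-window means of frame-level low-level descriptors
  (F0, voicing probability, zero-crossing rate and 20 MFCCs over 93 ms
  windows with a 70 ms hop), z-scored on the training split.

All three modalities share a grid of 2 s windows with a 1 s hop. Predictors
are single-hidden-layer LSTMs (implemented on a small numpy autodiff engine;
no deep-learning framework is required) with three fusion strategies:
feature fusion (concatenated LSTM outputs), additive soft-attention fusion
(per-window softmax weights over the modalities, which double as
explanations), and decision fusion (convex score combination grid-searched
at step 0.05). Evaluation supports median dichotomization, thin-slice
chunking with chunk/video-level scoring, Acc = 1 − MAE / PCC / macro-F1
metrics, and fixed-split or repeated k-fold protocols. Explanation surfaces
are percentile-group dominant patterns (top/bottom 10 % videos → top-4
kinemes, top-5 AUs) and per-modality attention contributions (mean ± SE
over runs).

A first-class synthetic-data module generates multimodal corpora with known
ground truth (sinusoidal motion prototypes, trait scores from a
logistic-linear model on behavioral summary features), so the entire
pipeline is testable without any external dataset.

## CLI

```sh
# synthetic corpus (OpenFace-dialect pose/AU CSVs + LLD tables + manifest)
kinetraits generate --out corpus/ --n-videos 40 --duration-s 16 --seed 1

# kineme vocabulary from the training split (2 s windows, 50% overlap)
kinetraits learn-vocab --manifest corpus/manifest.csv --out vocab.npz --k 16

# per-window kineme / AU / speech feature blocks
kinetraits encode --manifest corpus/manifest.csv --vocab vocab.npz --out enc/

# train + evaluate (models: kineme, au, speech, ff, af, df)
kinetraits evaluate --encodings enc/encodings.csv --manifest corpus/manifest.csv \
    --trait trait1 --models speech,df --protocol fixed-split --level video

# percentile-dominant kineme/AU explanation report
kinetraits explain --encodings enc/encodings.csv --manifest corpus/manifest.csv \
    --out explanations.json
```

Every subcommand accepts `--config <yaml>` (key-value overrides) and
`--verbose`.

## Layout

```
src/kinetraits/
  synthetic.py   ground-truth corpus generator + writer
  io.py          pose/AU/WAV/LLD/manifest readers and writers
  kineme.py      segment matrix, NMF+GMM vocabulary, NNLS assignment
  encoding.py    one-hot kinemes, dominant AUs, LLD extraction, z-scoring
  nn/            numpy autodiff engine, LSTM cell, Adam
  models.py      unimodal / feature-fusion / attention-fusion / decision fusion
  evaluation.py  dichotomization, thin slices, metrics, protocols
  explain.py     percentile patterns, attention contributions
  cli.py         click command group
```
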