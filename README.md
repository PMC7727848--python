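# chanwise

Cross-subject EEG emotion recognition from channel-wise correlation
features and a two-layer stacked LSTM.

A sliding window of `L*K*N` samples per channel is cut into `K*N` segments
of length `L`; each segment is reduced to its mean, and for each of the
`N` time steps the `C x C` Pearson correlation matrix of the `K` segment
means is computed. The strict upper triangle of each matrix (length
`C*(C-1)/2`: 496 for 32 channels, 1891 for 62) is flattened and the
`N`-step sequence of vectors is classified by a two-layer stacked LSTM
(hidden size 256, dropout before the fully connected softmax head, trained
with RMSProp on cross-entropy). With the default `L=2, K=8, N=10` one
window spans 1.25 s at 128 Hz and 0.8 s at 200 Hz.

The package ships:

- `chanwise.io` — recording containers (NPZ/MAT, optional EDF via
  `pyedflib`), pre-stimulus trimming, 1–9 rating binarization at 5,
  valence/arousal quadrant labels, thin DEAP/SEED layout adapters.
- `chanwise.features` — windowing, segment means, channel-wise Pearson
  matrices, upper-triangle flattening, and the stride-`L*K`
  sliding-window augmentation (adjacent windows share `N-1` of their `N`
  features).
- `chanwise.model` — the stacked-LSTM classifier implemented directly on
  NumPy (forward, full backpropagation through time, RMSProp), with
  seeded, bitwise-reproducible training and hidden-feature extraction.
- `chanwise.evaluation` — k-fold cross-validation (both the leaky
  `random_mixed` protocol and an honest `subject_wise` alternative),
  confusion matrices, and a one-at-a-time L/K/N hyperparameter sweep.
- `chanwise.synth` — synthetic multichannel recordings whose
  inter-channel correlation is a subject-specific base pattern plus a
  sparse emotion-specific perturbation (AR(1) noise mixed through a
  Cholesky factor), used as the test and benchmark fixture.
- `chanwise.viz` / `chanwise.cli` — correlation heatmaps (red/white/green,
  fixed [-1, 1] bounds), PCA embedding of hidden features, sweep plots,
  and a `chanwise` command-line interface.

## CLI

```sh
chanwise simulate  --out data --seed 1 --n-subjects 4 --channels 8 \
                   --trial-seconds 10 --magnitude 0.6
chanwise extract   --data data --out feat -L 2 -K 8 -N 10
chanwise train-eval --features feat --out run --folds 5 --hidden-dim 32 \
                    --epochs 20 --seed 1
chanwise sweep     --data data --out sweep --n-values 3,5,10 --folds 3
chanwise plot-features  --data data --trial 0 --out heatmap.png
chanwise plot-embedding --features hidden.npy --labels y.npy --out pca.png
```

Every command accepts `--config config.yaml` with sections `synth`,
`windowing`, `model`, `training`, `evaluation`; CLI flags override the
file, and each run writes its resolved configuration as JSON next to its
outputs.

## Notes

- `random_mixed` cross-validation lets windows from the same subject and
  stimulus land in train and test; it reproduces the original evaluation
  protocol but leaks subject identity. Use `--mode subject_wise` for an
  honest cross-subject estimate.
- A self-assessment rating of exactly 5 maps to "low" by default;
  `binarize_rating(..., tie="high"|"drop")` selects the alternatives.
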