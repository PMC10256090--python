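# beeradar

Simulation and classification of honeybee hive-entrance activity from
5.8 GHz continuous-wave Doppler radar IQ recordings.

The package provides the full pipeline:

1. **`beeradar.sim`** — physics-based synthesis of two-channel (I/Q)
   baseband recordings: bee flights with body Doppler and wingbeat
   phase-modulation sidebands, wind-shake and vibration clutter, and a
   modeled receiver chain (VGA noise, first-order 408 Hz IF low-pass,
   AC-coupled sound-card input, faint ~1 kHz equipment tone, wideband
   recording-noise floor).
2. **`beeradar.segmentation`** — fixed-grid 0.4 s windows with 0.1 s nominal
   overlap and a flexible final overlap (a 0.6 s signal becomes two 0.4 s
   windows overlapping by 0.2 s), plus single-label window assignment from a
   ground-truth event timeline.
3. **`beeradar.features`** — Log Area Ratio vectors from
   autocorrelation-method LPC (Levinson–Durbin), with rational-ratio
   resampling, per-channel/per-sub-window encoding, LPC spectral envelopes
   and STFT spectrograms.
4. **`beeradar.classify`** — hierarchical RBF-SVM pathways
   (P1: one four-way model; P2: background → hover → in/out cascade;
   P3: background → three-way), with Gaussian-process Bayesian
   hyperparameter optimization, stratified k-fold cross-validation and
   accuracy / weighted precision–recall / macro-F1 metrics.
5. **`beeradar.benchmarks`** — synthetic window datasets and the sweep
   experiments: accuracy vs sampling rate, vs LPC order, vs sub-window size;
   per-channel feature budgets; per-class spectral-envelope standard
   deviation.

## CLI

```sh
# synthesize a labelled scene (2-channel WAV + timeline CSV)
beeradar simulate --seed 1 --duration 30 --out scene.wav --labels scene.csv

# cut into labelled 0.4 s windows (one WAV per window + manifest)
beeradar segment --wav scene.wav --labels scene.csv --out windows/

# encode windows as LAR features
beeradar extract --manifest windows/manifest.csv --rate 3500 --order 100 \
    --channels iq --out features.csv

# train a pathway and evaluate
beeradar train --features features.csv --pathway P1 --budget 30 --seed 1 --out model/
beeradar evaluate --model model/ --features features.csv --report metrics.json

# benchmark sweeps on synthetic datasets
beeradar sweep rate --seeds 1,2,3 --out rate_sweep.csv
```

Timeline CSVs use the header `label,start_s,end_s` with labels in
`{inward, outward, hover, background}`; WAV channel 0 is I and channel 1
is Q.

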