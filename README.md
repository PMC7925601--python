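# speechtrf

Word-level encoding models for continuous-speech EEG, exercised end-to-end on
synthetic cohorts.

The package implements the full analysis chain used to study how listeners'
brains track the lexical and semantic predictability of natural speech:

- **`speechtrf.synthetic`** — forward model: category-structured random
  embeddings, Markov-chain training corpora, time-aligned transcripts
  (~190 words/min, 334 ± 140 ms word durations), and multichannel EEG built by
  convolving content-word impulse trains with N400-like kernels plus 1/f,
  white and shared-artifact noise. Two-group cohorts support injected latency
  shifts, per-feature gain manipulations, and a verbal-fluency covariate
  linked to the semantic gain.
- **`speechtrf.features`** — per-word regressors: semantic dissimilarity
  (1 − Pearson correlation between a word's embedding and the average of its
  preceding content-word context, sentence-bounded or fixed-window),
  5-gram surprisal from an interpolated modified Kneser–Ney model
  (`speechtrf.ngram`), distribution-matching normalization, and impulse-series
  construction including the onset nuisance regressor.
- **`speechtrf.preprocess`** — polyphase downsampling, zero-phase 0.5–8 Hz
  Butterworth band-pass, the 2.5× leave-one-out standard-deviation bad-channel
  rule, spherical-spline interpolation, mastoid referencing, and MCCA group
  denoising (`speechtrf.mcca`).
- **`speechtrf.trf`** — lagged ridge regression (`(SᵀS + λI)⁻¹Sᵀr`) with
  leave-one-trial-out cross-validation over a 0.1–1000 λ grid, permutation-null
  prediction deltas (impulse heights shuffled, positions fixed), and
  N400 trough-latency extraction in the 200–600 ms window.
- **`speechtrf.stats`** — Anderson–Darling + 1.5 IQR gated test battery
  (t / paired t vs Mann–Whitney / Wilcoxon, Kruskal–Wallis), running paired
  t-test with Benjamini–Hochberg FDR, Cohen's d, and age-controlled partial
  correlation.
- **`speechtrf.pipeline`** — experiment orchestration: simulate → features →
  preprocess → fit → stats, with YAML configs, deterministic seeding,
  machine-readable reports, and replications of the group-contrast,
  context-window-robustness and fluency-correlation analyses.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (ridge-oracle
equivalence, kernel/latency/fluency recovery, permutation-null soundness,
Kneser–Ney and statistics oracles, MCCA benefit, preprocessing contracts) at
reduced synthetic scale; the whole suite runs in a few minutes on one CPU.

## CLI

```sh
speechtrf simulate --seed 1 --out out/            # synthetic cohort + ground truth
speechtrf features --transcript t.tsv --embeddings e.txt --corpus c.txt \
    --context sentence --out features.tsv         # score a real transcript
speechtrf full --config experiment.yaml --out out # full experiment + report
```

Configs are produced by `speechtrf.pipeline.default_config()` (CI scale:
8 subjects/group, 32 channels, 4 × 60 s trials) and serialized with
`ExperimentConfig.to_yaml`; a paper-scale profile is
`default_config(n_per_group=19, n_channels=128, trial_duration_s=180)`.

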