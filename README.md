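# capnet

Analysis toolkit for recurring **transient co-activation patterns (CAPs)** in
band-limited envelope data and their correspondence with **time-averaged
resting-state networks (RSNs)** estimated by temporal ICA — implemented as a
tested, reusable pipeline exercised end-to-end on synthetic cohorts with
planted ground truth.

## What it does

- **`capnet.synthetic`** — synthetic cohorts: hemisphere-symmetric /
  hierarchical spatial templates, semi-Markov state sequences with
  configurable dwell times (~tens of ms) and occurrence rates, ROI envelope
  frames, and an oscillation mode (amplitude-modulated alpha carriers
  projected through a random lead field). All generative choices are
  stand-ins — there is no empirical generative model — and every generator is
  bit-reproducible under a fixed seed.
- **`capnet.inverse`** — minimum-norm source estimation
  `S = L' (LL' + λI)⁻¹ Φ` with per-frame λ selection by generalized
  cross-validation and 3-SD outlier repair of the λ series.
- **`capnet.envelope`** — zero-phase alpha-band (8–12 Hz) Butterworth
  filtering, Hilbert instantaneous amplitudes, node→ROI averaging, and
  z-scoring (per-ROI-across-time default; per-frame-across-ROIs selectable).
- **`capnet.rsn`** — 1-s / 1-Hz STFT spectral series, complex alpha-bin
  averaging, group temporal ICA (complex fixed-point, with a real-stacking
  fallback), IC time courses, and per-source envelope-regression beta maps.
- **`capnet.clustering`** — correlation-distance k-means over concatenated
  z-scored timeframes; participant- and group-level CAP maps (optionally from
  finer-resolution normalized frames).
- **`capnet.metrics`** — occurrence/lifetime run tables, CAP time courses,
  ANOVA + Bonferroni-corrected pairwise tests on log-transformed temporal
  metrics.
- **`capnet.compare`** — Fisher-z / dice similarity confusion matrices,
  optimal or user-supplied CAP–RSN matching (incl. one-to-two hemisphere-
  restricted pairs), permutation nulls, hemispheric symmetry index,
  leave-one-out inter-participant consistency, mixed-effect group contrasts,
  beta/consistency correlation, temporal correspondence.
- **`capnet.sweep`** — clustering reruns across k with the timeframe-overlap
  correspondence graph, and seed-stability reports.
- **`capnet.pipeline` / `capnet.cli`** — single-config orchestration with
  provenance sidecars.

## CLI

```sh
capnet run      --config config.yaml            # full pipeline
capnet simulate --config config.yaml --out sim/
capnet inverse  --leadfield L.npy --eeg phi.npy --out inv/
capnet envelope --in sources.npy --atlas atlas.tsv --band 8 12 --out env/
capnet cluster  --in env_dir/ --k 20 --seed 1 --out caps/
capnet metrics  --labels caps/ --out metrics/
capnet compare  --caps caps.npy --rsns rsns.npy --mirror mirror.tsv --out cmp/
capnet sweep    --in env_dir/ --k-list 10 12 15 18 20 --out sweep/
```

Minimal config:

```yaml
seed: 1
simulate: {n_roi: 100, k_true: 6, n_participants: 8, duration_s: 300, fs: 250, snr: 0.5}
cluster: {k: 6, n_init: 5}
compare: {n_perm: 10000}
sweep: {enabled: true, k_list: [4, 6, 8]}
```

## Conventions worth knowing

- State/cluster labels are 1-based; frame matrices are (space × time).
- Configured occurrence rates are renormalized when they are inconsistent
  with exhaustive state tiling; the achievable targets are recorded on each
  generated `StateSequence` as `target_rates_hz`.
- Dice thresholds are applied to signed maps at 20 % of the positive maximum
  by default (`use_abs=True` for magnitude maps).
- Permutation p-values use the add-one convention
  `p = (1 + #{null ≥ obs}) / (1 + n_perm)`, with identity relabelings
  permitted.
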