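# glimpsetrf

Neural encoding analysis of **glimpsed and masked speech** in two-talker
listening, built around banded-ridge temporal response functions (TRFs).

When two people speak at once, each talker's speech alternates between
*glimpsed* moments — spectrotemporal regions where that talker's energy
exceeds the background by at least a threshold SNR — and *masked* moments
where it is buried.  This package implements the full analysis chain that
asks how auditory cortex encodes the two kinds of speech:

- **Acoustic features**: multiband spectrograms (10 log-spaced bands,
  50 Hz–8 kHz, 100 Hz frame rate) and acoustic *edges* (half-wave rectified
  temporal derivative), split per talker into glimpsed
  (`min(edge_talker, edge_mixture)`) and masked
  (`max(edge_talker − edge_mixture, 0)`) components, which sum exactly back
  to the talker's edges.
- **Phonetic features**: forced-alignment phoneme tiers mapped to 22 binary
  articulatory features, split by each phoneme's *glimpse ratio*

  `ratio_glimpse = |spectrogram_talker ≥ spectrogram_background · 10^(θ/20)| / |spectrogram_talker|`

  computed over a 100-band spectrogram, so that
  glimpsed + masked regressors reconstruct the binary features exactly.
- **Encoding models**: mass-univariate TRFs (lags 0–500 ms) fit by the SVD
  solution to *banded* ridge regression — one L2 penalty per feature group —
  with the sequential tuning schedule (joint polar search over the first two
  groups, then one group at a time, all lambdas frozen afterwards) and
  5-fold cross-validated Fisher-z prediction accuracy.
- **Inference**: feature ablation (baseline vs null model Δz), shuffled-
  feature nulls per electrode, the glimpse-SNR threshold sweep, TRF power
  time courses and peak latencies, Wilcoxon/paired-t latency comparisons,
  Spearman anatomical gradients — all population-level p-values from a
  **hierarchical bootstrap** (resample subjects, then electrodes within
  subjects; N_boot = 10⁴) that respects the nesting of electrodes in
  subjects.
- **Synthetic data**: a generator producing two-talker band spectrograms
  with pseudo-phoneme/word structure and neural responses obtained by
  running the encoding model forward from ground-truth TRFs, so every stage
  is testable against a known truth without any recording.

## Worked example

```python
import glimpsetrf as g
from glimpsetrf import stats

# a synthetic "non-primary cortex" experiment: 7 subjects x 10 electrodes,
# 10 min at 100 Hz, glimpsed phonetic features encoded at 190 ms and masked
# at 285 ms, noise set so the oracle prediction correlation is ~0.3
ds = g.generate_dataset(g.make_scenario_presets()["stg_like"], seed=1)

fit = g.fit_trf(ds.bank, ds.responses,
                {n: 3e5 for n in ds.bank.names}, n_folds=None)
for group in ds.bank.names:
    curve, _ = stats.trf_power_timecourse(fit.group_weights(group))
    print(group, stats.encoding_latency(curve, fit.lag_ms))
```

prints

```
glimpsed_phonetic 190.0
masked_phonetic 285.0
```

— the TRF power time course of each feature group peaks at its generating
latency (ms).  Comparing per-electrode latencies,

```python
gl = stats.per_electrode_latencies(fit.group_weights("glimpsed_phonetic"), fit.lag_ms)
ml = stats.per_electrode_latencies(fit.group_weights("masked_phonetic"), fit.lag_ms)
comp = stats.latency_comparison(gl, ml, paired_subject_ids=ds.subject_ids, seed=0)
print(round(comp.paired_mean_diff_ms), comp.bootstrap_p)
```

```
94 0.0005
```

masked features lag glimpsed features by ~95 ms on average, significant by
the hierarchical bootstrap (p reported at its 1/N_boot floor is shown as the
smallest representable value).

A command-line interface wraps the same pipeline:

```bash
glimpse-trf simulate --preset stg_like --seed 7 --out data/
glimpse-trf run --config analysis.yaml
```

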