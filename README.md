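# dyadsync

Interpersonal neural synchronization (INS) analysis for fNIRS
hyperscanning.

When two people talk, their cortical hemodynamics synchronize.
`dyadsync` implements the full analysis chain used to quantify that
coupling from two-person oxygenated-hemoglobin (HbO) recordings in
turn-taking communication paradigms — e.g. cross-lingual conversation
through an interpreter, where consecutive interpreting delays the speech
relative to the speaker's gestures and shifts the listener's neural
response by tens of seconds.  Because raw hyperscanning datasets of this
kind are typically shareable only on request, the package ships a
synthetic dyad generator with full ground truth, so every stage of the
pipeline is testable end to end without any data download.

## The method

For each channel pair (one channel on participant A, one on participant
C) the pipeline computes:

1. **Preprocessing** — trim the first and last 30 s, subtract the
   per-channel linear trend, and repair motion artifacts with *temporal
   derivative distribution repair* (TDDR): the first differences of the
   fast component of the signal are re-weighted with Tukey's biweight
   (c = 4.685) on MAD-standardized residuals and re-integrated, which
   removes spikes and sharp baseline shifts without touching the
   hemodynamic band.  No band-pass filter is applied before coherence.

2. **Wavelet transform coherence (WTC)** — with Morlet wavelets
   (ω₀ = 6) on 106 geometric scales from 0.3 to 128 s,

   R²(s,t) = |S(s⁻¹ W_xy)|² / ( S(s⁻¹|W_x|²) · S(s⁻¹|W_y|²) ),

   where W are continuous wavelet transforms, W_xy the cross-spectrum
   and S a smoothing operator (Gaussian in time with std ∝ scale, boxcar
   across scales).  Coherence is converted to Fisher z = atanh(√R²).

3. **INS increase** — Fisher-z coherence averaged over the task period,
   minus the same quantity from the condition-matched resting baseline
   (rest with rain sounds for the consecutive-interpreting condition CI;
   silent rest for simultaneous interpreting SI and mother-tongue
   retelling CC).

4. **Time-lagged INS** — participant C's series is shifted by −26 … +26 s
   in 1 s steps, both series truncated to the overlap, and the whole
   coherence pipeline recomputed, giving lead–lag profiles of coupling.

5. **Inference** — frequency bands of interest are selected by a
   permutation test on per-scale repeated-measures F statistics
   (max-F null, 99th percentile, 1000 permutations); condition contrasts
   use paired t-tests over all channel pairs and lags with Bonferroni
   correction; significant couplings are validated against a
   pseudo-dyad null (re-pairing participants who never interacted); and
   per-phase INS (with the ~6 s hemodynamic delay-to-peak) is correlated
   with behavioral scores.

## Worked example

Simulate eight dyads whose CH1–CH2 pair carries a 0.025 Hz shared
component, delayed by 17 s on C, strong under SI (70% of channel
variance) and weak under CI (10%), then run the full pipeline:

```python
from dyadsync import (SimulationConfig, CouplingSpec, PipelineConfig,
                      run_pipeline)

config = PipelineConfig(
    simulation=SimulationConfig(
        n_dyads=8, n_channels=2, duration_s=300.0,
        conditions=("CI", "SI"),
        couplings=[CouplingSpec(channel_pair=("CH1", "CH2"),
                                center_freq=0.025, lag_s=17.0,
                                strength={"SI": 0.7, "CI": 0.1},
                                conditions=("CI", "SI"))]),
    scale_min=4.0, scale_max=50.0, n_scales=16, trim_s=0.0,
    max_lag_s=20, band=(0.020, 0.032), validation_n_perm=100, seed=7)

results = run_pipeline(config)

test = results["group_test"]
best = min(test.p_values, key=test.p_values.get)
print(f"strongest contrast: pair {best[0]}, lag {best[1]} s")
print(f"t = {test.t_values[best]:.3f}, p = {test.p_values[best]:.2e} "
      f"(Bonferroni m = {test.m})")
v = results["validation"]
print(f"pseudo-dyad null: observed {v['observed']:.3f}, "
      f"two-tailed p = {v['p_two_tailed']:.3f}")
```

prints

```
strongest contrast: pair ('CH1', 'CH2'), lag 12 s
t = -7.434, p = 1.45e-04 (Bonferroni m = 164)
pseudo-dyad null: observed -0.276, two-tailed p = 0.000
```

The paired t is strongly negative — the CI-minus-rest INS increase at
the coupled pair is far below the SI-minus-rest increase, exactly the
injected contrast — and it survives Bonferroni correction over all 164
(pair, lag) comparisons.  The observed statistic also lies outside the
pseudo-dyad null, confirming the coupling is specific to the true
pairings.  Note the lead–lag profile of a narrowband coupling is broad:
t is nearly constant from lag 12 to 20 s, so single-dyad lag estimates
carry a few seconds of uncertainty (group averages recover the injected
17 s; see the reproduction study below).

A command-line interface mirrors the stages
(`dyadsync simulate | preprocess | wtc | ins | select-bands |
group-test | validate | correlate | run`); every subcommand takes
`--seed` and a YAML config.

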