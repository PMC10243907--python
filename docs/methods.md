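# Methods

This note documents the models, parameter choices and numerical
conventions behind `dyadsync`, and what the synthetic-data studies do
and do not establish about real recordings.

## Signal model and scope

The pipeline starts from oxygenated-hemoglobin (HbO) concentration
series sampled at 10 Hz, 26 channels per participant (a 3×5 left
fronto-temporo-parietal patch plus a 2×2 right-TPJ patch).  Conversion
from raw optical intensities (modified Beer–Lambert) is out of scope;
so is anatomical labeling — channel→region tags ship as a static,
explicitly synthetic lookup table (`dyadsync.io.DEFAULT_REGION_LABELS`)
whose only load-bearing entries are CH15→lTPJ, CH24→rTPJ and
CH17/CH8→lIFG.  Only participants A and C (the interlocutors) are
modeled; the interpreter B is never analyzed.

Time is seconds, zero-based from recording start; all phase and block
windows are half-open `[start, start+duration)`.

## Preprocessing

**Trimming** removes the first and last 30 s of each task (instrument
settle-in/tear-down).  **Detrending** subtracts a per-channel ordinary
least-squares polynomial; the order is exposed and defaults to linear,
the simplest model consistent with "subtract the trend".  Note a
boundary subtlety: a sine phased at the record start is *not* orthogonal
to a ramp even over integer periods, so linear detrending can tilt such
a component by several percent; only even-symmetric oscillations about
the record midpoint pass through untouched.

**TDDR** (temporal derivative distribution repair) splits each
detrended channel at 0.5 Hz with a zero-phase 3rd-order Butterworth
filter and robustly re-weights the first differences of the *fast*
component: iterate weighted mean μ, MAD scale σ = 1.4826·median|d−μ|,
Tukey biweight w = (1−u²)² for u = |d−μ|/(4.685σ) < 1 else 0, until the
largest weight change falls below 1e-8 (max 50 iterations); then
re-integrate w·(d−μ) and add back the slow component and the trend.
Applying the repair to the fast component is a deliberate choice for
10 Hz data: single-sample motion spikes live almost entirely above
0.5 Hz, and the hemodynamic band below the cutoff must pass through
untouched.  The measured behavior (the acceptance study recomputes it)
is >90% suppression of a 20-SD single-sample spike with <3% change in a
0.025 Hz sinusoid's fitted amplitude.  Degenerate inputs: a constant
derivative gives σ = 0, meaning nothing is an outlier — the channel is
returned unchanged (constants and ramps are exact fixed points).
Non-convergence proceeds with the last weights and logs a warning.

No band-pass filtering is applied before coherence: frequency
selection happens statistically, after the wavelet stage.

## Wavelet coherence

Morlet wavelets with ω₀ = 6; scale grid geometric with 106 points from
0.3 s to 128 s (`scales[k] = 0.3·(128/0.3)^(k/105)`), Fourier period
= scale · 4π/(ω₀+√(2+ω₀²)) ≈ 1.033·scale.  The CWT is FFT-based
(zero-padding to the next power of two, analytic wavelet, L2
normalization); the frequency-domain filter bank is cached, which makes
the 53-lag scans tractable on one core.

The coherence smoothing operator S acts per scale along time with a
Gaussian of std = scale/√2 seconds (applied analytically in the
frequency domain, with padding beyond 8σ so circular wrap-around is
below 1e-9), then across scales with a boxcar of 0.6 decades in
log-scale, rounded to a whole number of grid steps.  Both kernels are
normalized: a constant field is preserved away from the record edges.
Without S, R² ≡ 1 identically — the test suite asserts this degeneracy
to guard the smoothing step.  The cone of influence (max valid period =
1.033·d/√2 at distance d from the nearest edge) is computed and stored
but not excluded from task averages by default; exclusion was left as a
flag because task averaging over whole blocks is the analysis
convention the pipeline reproduces.

Fisher z is applied to r = √R² (correlation analogy), with r capped at
1−1e-7; applying atanh to R² directly is available as a switch
(`square_root=False`).  The choice matters little for band averages but
is stated because either reading of "Fisher z of coherence" is
defensible.

## INS increase and lags

Task averaging is z-then-average (Fisher transform each time–scale
cell, then average over task samples), the variance-stabilized order.
The matched baselines are enforced by a guard: CI must be corrected
against rest-with-rain-sounds, SI and CC against silent rest — the rest
condition shares the auditory environment of its task.

Lagged INS shifts C by whole seconds (−26 … +26), truncates both series
to the overlap (never wrap-around, which would fabricate coupling
across the record boundary), and recomputes the full WTC on the shifted
series.  Lag 0 reproduces the unlagged pipeline bit for bit.  Task
windows under lag follow a "both timelines" rule: a sample counts as
task only if it falls inside a task block on both participants' clocks,
which reduces to trimming |lag| seconds off each block end and makes
lagged INS exactly symmetric (up to lag negation) under swapping A and
C.  Rest baselines are computed once, unlagged, by default: rest has no
lead–lag structure, so re-lagging it would only add estimator noise
(a `lag_rest=True` switch recomputes it per lag for strict symmetry
with the task arm).

Phase-resolved averages shift each 45 s turn-taking phase forward by
the hemodynamic delay-to-peak (default 6 s) and pool phases of the same
type (A-speaking vs C-speaking) across turns, yielding one value per
dyad per direction for the score correlations.

## Inference

Per-scale repeated-measures one-way F across conditions (error = dyad ×
condition interaction; for two conditions F = t² of the paired t, which
the tests verify numerically).  The permutation null shuffles condition
labels within each dyad and records the maximum F across scales,
controlling family-wise error over the frequency axis; a per-scale
pointwise threshold is available behind a flag.  The threshold is the
99th percentile of the null maxima, taken as the `higher` order
statistic — with finitely many permutations, linear percentile
interpolation is anti-conservative (≈1.5% exceedance at n_perm = 200
instead of 1%).  Clusters of consecutive supra-threshold scales
separated by at most one scale step are merged into bands, since heavy
across-scale smoothing makes hairline gaps meaningless.  Degenerate
permutations (zero error variance) return F = 0.

Group contrasts are paired t-tests per (channel pair, lag), Bonferroni
m = n_pairs × n_lags (676 × 53 = 35,828 for the full scan), α = 0.05.

The pseudo-dyad permutation re-pairs participant A of one dyad with
participant C of another; the statistic function receives the
assignment, so the same machinery accepts any exchangeable unit —
including a channel-shuffle null if a caller prefers permuting channel
pairs instead of dyads.  When n! ≤ n_perm the null is enumerated
exhaustively (identity included, so the observed value is an element of
its own null); otherwise random permutations are drawn and flagged as
sampled-with-replacement.  The orchestrated pipeline caches the n×n
matrix of per-(A_i, C_j) statistics so any number of permutations costs
only lookups.  The default two-tailed area is 5%, with stricter levels
available.

## Synthetic data generator

Each channel is unit-variance noise: a 1/f background (spectral
exponent 1.0 by default, the canonical resting-hemodynamics slope),
narrowband cardiac (1.0 Hz), respiratory (0.3 Hz) and Mayer-wave
(0.1 Hz) oscillations with random phases at relative amplitudes
0.4/0.3/0.3, and white sensor noise (SD 0.2).  Inter-brain coupling is
a band-limited Gaussian process — white noise shaped by a Gaussian
spectral window — added to one channel of A and, delayed by an integer
number of samples, to the paired channel of C.  Coupled channels mix
`√(1−strength)·noise + √strength·shared` with both pieces normalized,
so `strength` is exactly the shared-variance fraction (recovered
empirically to ±0.05 in the tests).  A stochastic band-limited process,
not a sinusoid, is used deliberately: coherence, not trivially perfect
correlation, is what the pipeline must recover.

The default coupling bandwidth is 0.006 Hz (Gaussian std), chosen so
the process fills a band of roughly 0.020–0.032 Hz width (FWHM ≈
0.014 Hz) — the width of the slow turn-taking band the analysis
targets.  A consequence worth knowing: the lead–lag profile of such a
narrowband coupling is intrinsically broad (the process decorrelates
over ~1/(2π·0.006) ≈ 26 s), so lag estimates from single cohorts
scatter by a couple of seconds around the injected value; the recovery
study therefore scores argmax hits within ±2 s.

Motion artifacts are Poisson-timed per channel: single-sample spikes
and persistent step shifts, amplitudes Gaussian in units of the channel
SD.  Rates default to zero; the artifact path is exercised explicitly
in tests and available for robustness studies.  Rest sessions share the
noise model but never the couplings.  Everything is keyed determinism:
(seed, dyad, condition) seeds a dedicated generator, so cohorts are
bit-reproducible and conditions can be regenerated independently.

What the generator does *not* emulate: task-evoked mean hemodynamic
responses (box-car HRF structure), spatial correlation between
neighboring channels, superficial/systemic physiology shared within a
participant, slow drifts beyond 1/f, and realistic inter-dyad
heterogeneity of SNR.  Passing the recovery studies therefore shows the
*pipeline* is correct and calibrated, not that effects of the simulated
size are what real recordings deliver; no public effect-size estimates
exist for power matching, and the default strengths (0.7 vs 0.1) were
chosen for test reliability.

## Validation studies and problem sizes

Two simulation studies (in `dyadsync.experiments`, rerun both by the
test suite and by `scripts/acceptance.py`):

* **Lag/band recovery** — cohorts of 10 dyads, 4 channels, 400 s
  sessions; coupling at 0.025 Hz, 17 s lag, strength 0.7 (SI) vs 0.1
  (CI); analysis on a 32-scale grid spanning periods 4–50 s with the
  full ±26 s lag scan.  Scored: argmax of the mean SI−CI band-averaged
  lag profile within 17±2 s, and permutation-selected band overlapping
  0.020–0.032 Hz.  These sizes keep one replicate near half a minute on
  a single core while leaving ≈10 coupling periods per record.
* **Type-I calibration** — coupling-free cohorts (10 dyads, one
  channel, 200 s, two task conditions vs shared rest), n_perm = 200;
  the fraction of runs selecting any band is compared against the
  nominal 1%.

## Known limitations

* The across-scale boxcar of 0.6 decades is heavy smoothing on coarse
  grids; selected bands are correspondingly wide, and band *edges*
  should not be over-interpreted.
* Lagged recomputation is O(n_lags) full WTC passes per pair; a full
  676-pair, 53-lag scan is hours of CPU, which is why the orchestrated
  pipeline accepts channel-pair subsets.
* The SNIRF adapter reads the minimal HbO-only slice of the format and
  ignores geometry, stimulus and auxiliary groups.
* Score correlations assume one behavioral score per dyad per
  direction; no hierarchical model is offered for raters or blocks.
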