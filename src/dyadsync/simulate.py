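"""Synthetic fNIRS dyad generator with full ground truth.

The raw hyperscanning data the pipeline was designed for is available
only on request, so every downstream stage is exercised on simulated
recordings that reproduce the statistical structure the analysis
assumes:

* per-channel background = 1/f noise plus cardiac (~1 Hz), respiratory
  (~0.3 Hz) and Mayer-wave (~0.1 Hz) oscillations plus white sensor
  noise;
* condition-dependent inter-brain coupling: a band-limited Gaussian
  process (white noise shaped by a Gaussian spectral window) shared by a
  designated channel of participant A and, delayed by a fixed lag, the
  paired channel of participant C.  Using a stochastic band-limited
  process rather than a sinusoid means wavelet coherence — not trivially
  perfect correlation — is the quantity the pipeline has to recover;
* optional motion artifacts: single-sample spikes and persistent
  baseline shifts at Poisson rates.

Coupled channels are built as
``sqrt(1-strength) * noise + sqrt(strength) * shared`` with both pieces
normalized to unit variance, so ``strength`` is exactly the fraction of
channel variance carried by the shared component.  Everything is
deterministic given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import (CI_PHASE_S, REST_FOR_CONDITION, Phase, Recording,
                 SessionLayout)

__all__ = [
    "CouplingSpec",
    "NoiseSpec",
    "ArtifactSpec",
    "SimulationConfig",
    "GroundTruth",
    "ArtifactEvent",
    "Cohort",
    "generate_dyad",
    "generate_cohort",
    "inject_motion_artifacts",
    "default_layout",
]


@dataclass(frozen=True)
class CouplingSpec:
    """One injected inter-brain coupling.

    The shared band-limited process is centered at ``center_freq`` Hz
    with Gaussian spectral ``bandwidth`` (std, Hz), added to channel
    ``channel_pair[0]`` of A and — delayed by ``lag_s`` seconds when
    positive — to ``channel_pair[1]`` of C.  ``strength`` is the variance
    fraction of the shared component, and the coupling is active only in
    the listed conditions (strength may be given per condition as a
    dict).
    """

    channel_pair: Tuple[str, str]
    center_freq: float = 0.025
    bandwidth: float = 0.006
    lag_s: float = 0.0
    strength: object = 0.5  # float, or {condition: float}
    conditions: Tuple[str, ...] = ("CI", "SI", "CC")

    def strength_in(self, condition: str) -> float:
        if condition not in self.conditions:
            return 0.0
        if isinstance(self.strength, dict):
            return float(self.strength.get(condition, 0.0))
        return float(self.strength)

    def validate(self, sampling_rate: float) -> None:
        strengths = (list(self.strength.values())
                     if isinstance(self.strength, dict) else [self.strength])
        for s in strengths:
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"strength {s} outside [0, 1]")
        if not 0.0 < self.center_freq < sampling_rate / 2.0:
            raise ValueError("center_freq must lie below the Nyquist frequency")
        if abs(self.lag_s) > 26.0:
            raise ValueError("|lag_s| must be <= 26 s")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Physiological + instrumental noise model for one channel.

    Defaults are chosen to look like resting HbO at 10 Hz: a 1/f
    background dominating the low frequencies, narrowband cardiac
    (~1 Hz), respiratory (~0.3 Hz) and Mayer-wave (~0.1 Hz) components
    of modest relative amplitude, and a little white sensor noise.
    Amplitudes are relative to the unit-variance 1/f background.
    """

    one_over_f_exponent: float = 1.0
    cardiac_freq_hz: float = 1.0
    cardiac_amplitude: float = 0.4
    respiratory_freq_hz: float = 0.3
    respiratory_amplitude: float = 0.3
    mayer_freq_hz: float = 0.1
    mayer_amplitude: float = 0.3
    white_sd: float = 0.2

    def __post_init__(self):
        for a in (self.cardiac_amplitude, self.respiratory_amplitude,
                  self.mayer_amplitude, self.white_sd):
            if a < 0:
                raise ValueError("noise amplitudes must be >= 0")


@dataclass(frozen=True)
class ArtifactSpec:
    """Motion-artifact rates (events/minute) and sizes (channel SDs)."""

    spike_rate: float = 0.0
    spike_amplitude_sd: float = 8.0
    shift_rate: float = 0.0
    shift_amplitude_sd: float = 3.0

    def __post_init__(self):
        if self.spike_rate < 0 or self.shift_rate < 0:
            raise ValueError("artifact rates must be >= 0")


@dataclass(frozen=True)
class ArtifactEvent:
    role: str
    channel: str
    kind: str          # "spike" | "shift"
    sample: int
    amplitude: float


@dataclass
class SimulationConfig:
    """Full description of a simulated cohort; (seed, config) determines
    every sample of every recording."""

    n_dyads: int = 10
    n_channels: int = 26
    sampling_rate: float = 10.0
    duration_s: float = 540.0
    conditions: Tuple[str, ...] = ("CI", "SI")
    couplings: List[CouplingSpec] = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0 or self.duration_s <= 0:
            raise ValueError("sampling_rate and duration_s must be positive")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        for c in self.couplings:
            c.validate(self.sampling_rate)
        self.channel_labels = [f"CH{k + 1}" for k in range(self.n_channels)]
        for c in self.couplings:
            for ch in c.channel_pair:
                if ch not in self.channel_labels:
                    raise ValueError(f"coupling names unknown channel {ch!r}")


@dataclass
class GroundTruth:
    """Everything injected into one simulated dyad session."""

    dyad_id: int
    condition: str
    couplings: List[CouplingSpec] = field(default_factory=list)
    shared_components: Dict[Tuple[str, str], np.ndarray] = field(default_factory=dict)
    artifact_events: List[ArtifactEvent] = field(default_factory=list)


_COND_CODE = {c: i for i, c in enumerate(("CI", "SI", "CC", "rest", "rest_rain"))}


def _rng_for(seed: int, dyad_id: int, condition: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(dyad_id), _COND_CODE[condition]])
    )


def _unit(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return x / sd if sd > 0 else x


def one_over_f_noise(rng: np.random.Generator, n: int, rate: float,
                     exponent: float) -> np.ndarray:
    """Unit-variance noise with power spectral density ~ 1/f**exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    return _unit(np.fft.irfft(spec * shaping, n))


def band_limited_noise(rng: np.random.Generator, n: int, rate: float,
                       center_freq: float, bandwidth: float) -> np.ndarray:
    """Unit-variance Gaussian process with Gaussian spectral envelope
    centered at ``center_freq`` (std ``bandwidth``, Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    window = np.exp(-0.5 * ((f - center_freq) / bandwidth) ** 2)
    window[0] = 0.0
    return _unit(np.fft.irfft(spec * window, n))


def _channel_noise(rng: np.random.Generator, n: int, rate: float,
                   spec: NoiseSpec) -> np.ndarray:
    t = np.arange(n) / rate
    x = one_over_f_noise(rng, n, rate, spec.one_over_f_exponent)
    for f0, amp in ((spec.cardiac_freq_hz, spec.cardiac_amplitude),
                    (spec.respiratory_freq_hz, spec.respiratory_amplitude),
                    (spec.mayer_freq_hz, spec.mayer_amplitude)):
        if amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            x = x + amp * np.sqrt(2.0) * np.sin(2 * np.pi * f0 * t + phase)
    if spec.white_sd > 0:
        x = x + spec.white_sd * rng.standard_normal(n)
    return _unit(x)


def generate_dyad(config: SimulationConfig, dyad_id: int,
                  condition: str) -> Tuple[Recording, Recording, GroundTruth]:
    """Simulate one dyad session (participants A and C) for one condition.

    Rest conditions never carry couplings; task conditions carry every
    coupling active in them, with the shared component delayed on C's
    channel by ``lag_s`` (which must be an integer number of samples).
    """
    rng = _rng_for(config.seed, dyad_id, condition)
    n = int(round(config.duration_s * config.sampling_rate))
    rate = config.sampling_rate
    labels = config.channel_labels

    data = {"A": np.empty((config.n_channels, n)),
            "C": np.empty((config.n_channels, n))}
    for role in ("A", "C"):
        for i in range(config.n_channels):
            data[role][i] = _channel_noise(rng, n, rate, config.noise)

    truth = GroundTruth(dyad_id=dyad_id, condition=condition)
    active = [] if condition.startswith("rest") else [
        c for c in config.couplings if c.strength_in(condition) > 0.0
    ]
    for c in active:
        lag_samples = c.lag_s * rate
        if abs(lag_samples - round(lag_samples)) > 1e-9:
            raise ValueError(
                f"lag {c.lag_s} s is not an integer number of samples at "
                f"{rate} Hz"
            )
        L = int(round(abs(lag_samples)))
        shared_full = band_limited_noise(rng, n + L, rate,
                                         c.center_freq, c.bandwidth)
        if c.lag_s >= 0:
            # positive lag: C lags A, so A sees the later segment
            shared_a, shared_c = shared_full[L:], shared_full[:n]
        else:
            shared_a, shared_c = shared_full[:n], shared_full[L:]
        s = c.strength_in(condition)
        ia = labels.index(c.channel_pair[0])
        ic = labels.index(c.channel_pair[1])
        data["A"][ia] = (np.sqrt(1 - s) * _unit(data["A"][ia])
                         + np.sqrt(s) * _unit(shared_a))
        data["C"][ic] = (np.sqrt(1 - s) * _unit(data["C"][ic])
                         + np.sqrt(s) * _unit(shared_c))
        truth.couplings.append(replace(c, strength=s))
        truth.shared_components[c.channel_pair] = shared_full

    rec_a = Recording("A", rate, data["A"], list(labels))
    rec_c = Recording("C", rate, data["C"], list(labels))

    spec = config.artifacts
    if spec.spike_rate > 0 or spec.shift_rate > 0:
        art_seed = int(rng.integers(0, 2**31 - 1))
        rec_a, ev_a = inject_motion_artifacts(rec_a, spec, art_seed)
        rec_c, ev_c = inject_motion_artifacts(rec_c, spec, art_seed + 1)
        truth.artifact_events = ev_a + ev_c
    return rec_a, rec_c, truth


def inject_motion_artifacts(recording: Recording, spec: ArtifactSpec,
                            seed: int) -> Tuple[Recording, List[ArtifactEvent]]:
    """Add Poisson-timed motion artifacts to every channel.

    Spikes are single-sample excursions; shifts are step changes
    persisting to the end of the record.  Amplitudes are Gaussian with
    std ``*_amplitude_sd`` channel standard deviations.  Returns the
    corrupted recording and the injected events as ground truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    out = recording.copy()
    minutes = recording.duration_s / 60.0
    events: List[ArtifactEvent] = []
    for i, ch in enumerate(recording.channel_labels):
        sd = recording.data[i].std()
        for kind, rate_pm, amp_sd in (
            ("spike", spec.spike_rate, spec.spike_amplitude_sd),
            ("shift", spec.shift_rate, spec.shift_amplitude_sd),
        ):
            if rate_pm <= 0:
                continue
            n_events = rng.poisson(rate_pm * minutes)
            for _ in range(n_events):
                k = int(rng.integers(0, recording.n_samples))
                amp = float(rng.normal(0.0, amp_sd) * sd)
                if kind == "spike":
                    out.data[i, k] += amp
                else:
                    out.data[i, k:] += amp
                events.append(ArtifactEvent(recording.participant_role,
                                            ch, kind, k, amp))
    return out, events


def default_layout(condition: str, duration_s: float) -> SessionLayout:
    """Session layout used for simulated data.

    CI sessions are filled with 90 s turn-takings (two 45 s phases: A
    speaks while C listens to the reverse interpretation, then C speaks
    while A listens to the forward interpretation).  SI, CC and the rest
    conditions get a single task block with no phase structure, since
    only CI's phases enter phase-resolved analyses.
    """
    layout = SessionLayout(condition, blocks=[(0.0, duration_s)])
    if condition == "CI":
        turn_len = 2 * CI_PHASE_S
        n_turns = int(duration_s // turn_len)
        phases = []
        for k in range(n_turns):
            t0 = k * turn_len
            phases.append(Phase(t0, CI_PHASE_S, "A_speak_C_listen", k))
            phases.append(Phase(t0 + CI_PHASE_S, CI_PHASE_S, "C_speak_A_listen", k))
        layout = SessionLayout(condition, blocks=[(0.0, duration_s)], turns=phases)
    return layout


@dataclass
class Cohort:
    """A simulated multi-dyad study: recordings per dyad per condition
    (tasks and matched rests), layouts, and all injected ground truth."""

    config: SimulationConfig
    recordings: Dict[int, Dict[str, Tuple[Recording, Recording]]]
    layouts: Dict[str, SessionLayout]
    ground_truth: Dict[Tuple[int, str], GroundTruth]

    @property
    def dyad_ids(self) -> List[int]:
        return sorted(self.recordings)

    def conditions_present(self) -> List[str]:
        any_dyad = self.recordings[self.dyad_ids[0]]
        return list(any_dyad.keys())


def generate_cohort(config: SimulationConfig,
                    rest_duration_s: Optional[float] = None) -> Cohort:
    """Simulate the whole cohort: every dyad in every task condition plus
    the matched coupling-free rest baselines (rest with rain sounds for
    CI; silent rest for SI and CC)."""
    if config.n_dyads < 2:
        raise ValueError("need at least 2 dyads for group statistics")
    rest_dur = rest_duration_s if rest_duration_s is not None else config.duration_s

    needed_rests = sorted({REST_FOR_CONDITION[c] for c in config.conditions})
    sessions = list(config.conditions) + needed_rests

    recordings: Dict[int, Dict[str, Tuple[Recording, Recording]]] = {}
    truths: Dict[Tuple[int, str], GroundTruth] = {}
    for d in range(config.n_dyads):
        recordings[d] = {}
        for cond in sessions:
            cfg = config
            if cond.startswith("rest") and rest_dur != config.duration_s:
                cfg = replace(config, duration_s=rest_dur)
            ra, rc, gt = generate_dyad(cfg, d, cond)
            recordings[d][cond] = (ra, rc)
            truths[(d, cond)] = gt

    layouts = {
        cond: default_layout(
            cond, rest_dur if cond.startswith("rest") else config.duration_s)
        for cond in sessions
    }
    return Cohort(config, recordings, layouts, truths)
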