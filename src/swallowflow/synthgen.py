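"""Synthetic dual-axis swallowing-accelerometry generator.

No raw accelerometry waveforms from the original protocol are publicly
available, so this module generates labelled surrogate data whose *protocol
structure* and *feature-level statistics* match the study design the package
analyses:

* 17 healthy participants, each contributing 17 recorded sequences: every
  stimulus x task combination twice, plus a third water-discrete repetition;
* four swallows per sequence, with short inter-swallow gaps in the sequential
  (continuous drinking) task and long gaps in the discrete task;
* four stimuli ordered by viscosity (water < barium < nectar < honey) with
  stimulus-dependent swallow duration (means from the published per-task
  duration tables) and signal regularity increasing with viscosity
  (implemented as a broadband-noise amplitude that decreases with viscosity);
* an acquisition chain: optional AR coloration, 0.1 Hz - 3 kHz bandpass,
  10x gain, and input-referred sensor noise, so that noise-only baseline
  recordings carry the chain's spectral signature for inverse-filter fitting.

The swallow waveform itself (a biphasic burst envelope modulating a
low-frequency oscillation, with a quadratic asymmetry that controls the
negative skewness of the A-P amplitude distribution) is a modelling choice;
only its feature-level consequences are treated as meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .core import STIMULI, TASKS, DualAxisRecording, GroundTruth, RecordingMeta

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Invalid generator configuration (e.g. unstable coloration polynomial)."""


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass
class StimulusProfile:
    """Latent per-stimulus generator parameters.

    noise_amplitude is the broadband-noise RMS relative to the structured
    component's RMS: it is the regularity knob (lower = more regular signal,
    i.e. higher entropy-rate and lower Lempel-Ziv complexity downstream).
    skew_shape in [0, 1] controls the A-P amplitude asymmetry: *lower* values
    give a more negatively skewed A-P amplitude distribution.
    """

    name: str
    viscosity_rank: int
    mean_duration_discrete: float
    mean_duration_sequential: float
    noise_amplitude: float
    skew_shape: float

    def __post_init__(self) -> None:
        if self.mean_duration_discrete <= 0 or self.mean_duration_sequential <= 0:
            raise ValueError("mean durations must be positive")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")

    def mean_duration(self, task: str) -> float:
        if task == "discrete":
            return self.mean_duration_discrete
        if task == "sequential":
            return self.mean_duration_sequential
        raise ValueError(f"unknown task {task!r}")


def make_default_profiles() -> dict[str, StimulusProfile]:
    """The four default stimulus profiles, keyed by stimulus name.

    Mean durations are the published per-task stimulus means (discrete:
    2.097/2.056/2.228/2.324 s; sequential: 1.463/1.533/1.643/1.747 s for
    water/barium/nectar/honey).  Noise amplitudes decrease strictly with
    viscosity so that signal regularity increases with viscosity, and
    skew_shape increases with viscosity so that the thickened juices yield a
    less negatively skewed A-P amplitude distribution.
    """
    return {
        "water": StimulusProfile("water", 1, 2.097, 1.463, 0.34, 0.25),
        "barium": StimulusProfile("barium", 2, 2.056, 1.533, 0.26, 0.24),
        "nectar": StimulusProfile("nectar", 3, 2.228, 1.643, 0.18, 0.45),
        "honey": StimulusProfile("honey", 4, 2.324, 1.747, 0.13, 0.55),
    }


@dataclass
class AcquisitionModel:
    """Linear acquisition chain: sensor noise -> AR coloration -> bandpass -> gain.

    Sensor noise is input-referred (it enters before the chain) so that
    noise-only baseline recordings are colored by the chain — which is what
    makes them usable for inverse-filter estimation.  ``band_low=None``
    disables the bandpass; an empty ``coloration_ar_coeffs`` disables
    coloration.
    """

    gain: float = 10.0
    band_low: float | None = 0.1
    band_high: float | None = 3000.0
    coloration_ar_coeffs: tuple[float, ...] = (0.6, -0.2)
    sensor_noise_sd: float = 0.01

    def validate(self, sampling_rate: float) -> None:
        a = np.asarray(self.coloration_ar_coeffs, dtype=float)
        if a.size:
            roots = np.roots(np.concatenate([[1.0], -a]))
            if np.any(np.abs(roots) >= 1.0):
                raise ConfigurationError(
                    "coloration AR polynomial is unstable (root on/outside unit circle)")
        if self.band_low is not None:
            hi = self.effective_band_high(sampling_rate)
            if not (0 < self.band_low < hi <= sampling_rate / 2):
                raise ConfigurationError("bandpass edges must satisfy 0 < low < high <= Nyquist")

    def effective_band_high(self, sampling_rate: float) -> float:
        hi = self.band_high if self.band_high is not None else np.inf
        return min(hi, 0.99 * sampling_rate / 2)


@dataclass
class SyntheticConfig:
    """Full study-simulation configuration. Defaults reproduce the protocol
    at the original 10 kHz rate; tests and quick runs lower ``sampling_rate``."""

    n_participants: int = 17
    sampling_rate: float = 10_000.0
    seed: int = 0
    profiles: dict[str, StimulusProfile] = field(default_factory=make_default_profiles)
    coupling: float = 0.6
    participant_sd_duration: float = 0.3
    within_sd_duration: float = 0.15
    participant_sd_log_amp: float = 0.2
    participant_sd_log_noise: float = 0.1
    gap_discrete_s: float = 2.0
    gap_sequential_s: float = 0.2
    lead_in_s: float = 5.0
    tail_s: float = 0.5
    baseline_s: float = 5.0
    acquisition: AcquisitionModel = field(default_factory=AcquisitionModel)

    def __post_init__(self) -> None:
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError("coupling must lie in [0, 1]")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for name in ("participant_sd_duration", "within_sd_duration",
                     "participant_sd_log_amp", "participant_sd_log_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.acquisition.validate(self.sampling_rate)


@dataclass
class SessionPlan:
    """The ordered list of (stimulus, task, repetition) entries one
    participant records; the default plan has 17 entries."""

    participant_id: str
    entries: list[tuple[str, str, int]]


def default_session_plan(participant_id: str) -> SessionPlan:
    """Two repetitions of every stimulus x task combination plus a third
    water-discrete repetition: 17 entries, four planned swallows each."""
    entries = []
    for stimulus in STIMULI:
        for task in TASKS:
            for rep in (1, 2):
                entries.append((stimulus, task, rep))
    entries.append(("water", "discrete", 3))
    return SessionPlan(participant_id, entries)


@dataclass
class ParticipantEffects:
    """Random per-participant offsets (blocking structure for the Friedman
    design): additive duration offset (s), multiplicative amplitude and
    noise scales."""

    duration_offset: float = 0.0
    amp_scale: float = 1.0
    noise_scale: float = 1.0


def draw_participant_effects(config: SyntheticConfig,
                             rng: np.random.Generator) -> ParticipantEffects:
    return ParticipantEffects(
        duration_offset=rng.normal(0.0, config.participant_sd_duration),
        amp_scale=float(np.exp(rng.normal(0.0, config.participant_sd_log_amp))),
        noise_scale=float(np.exp(rng.normal(0.0, config.participant_sd_log_noise))),
    )


# ---------------------------------------------------------------------------
# swallow waveform
# ---------------------------------------------------------------------------

def draw_duration(profile: StimulusProfile, task: str, rng: np.random.Generator,
                  within_sd: float = 0.15, offset: float = 0.0,
                  max_retries: int = 50) -> float:
    """Draw one swallow duration (s) around the profile/task mean.

    Normal draw truncated below at 20% of the mean; non-positive draws are
    redrawn (bounded retries).
    """
    mean = max(profile.mean_duration(task) + offset, 0.4)
    lo = 0.2 * mean
    for _ in range(max_retries):
        d = rng.normal(mean, within_sd)
        if d >= lo:
            return float(d)
    raise RuntimeError("could not draw a positive swallow duration")


def generate_swallow(profile: StimulusProfile, task: str, rng: np.random.Generator,
                     sampling_rate: float = 10_000.0, coupling: float = 0.6,
                     effects: ParticipantEffects | None = None,
                     within_sd: float = 0.15,
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Generate one swallow: ``(ap_samples, si_samples, duration_s)``.

    The waveform is a structured component — a biphasic burst envelope
    modulating a low-frequency (8-14 Hz) oscillation, skewed by a quadratic
    asymmetry controlled by ``profile.skew_shape`` — plus additive broadband
    noise with RMS ``noise_amplitude`` relative to the structured component.
    The S-I channel mixes a smoothed copy of the shared source (fraction
    ``coupling``) with an independent oscillation.
    """
    eff = effects or ParticipantEffects()
    d = draw_duration(profile, task, rng, within_sd=within_sd,
                      offset=eff.duration_offset)
    n = int(round(d * sampling_rate)) + 1
    t = np.arange(n) / sampling_rate

    # biphasic envelope: a sharp early lobe and a broader late lobe
    c1, w1 = 0.30 * d, 0.13 * d
    c2, w2 = 0.62 * d, 0.20 * d
    env = np.exp(-0.5 * ((t - c1) / w1) ** 2) + 0.75 * np.exp(-0.5 * ((t - c2) / w2) ** 2)

    f0 = rng.uniform(8.0, 14.0)
    ph0, ph1, ph2 = rng.uniform(0, 2 * np.pi, size=3)
    osc = np.sin(2 * np.pi * f0 * t + ph0) + 0.4 * np.sin(2 * np.pi * 2.1 * f0 * t + ph1)
    shared = env * osc

    # quadratic asymmetry: lower skew_shape -> stronger negative skew of A-P.
    # Mean-centred afterwards: vibration carries no net acceleration offset
    # (and a DC step would ring through the acquisition highpass).
    gamma = 0.8 * (1.0 - profile.skew_shape)
    peak = np.max(np.abs(shared)) or 1.0
    shared = shared - gamma * (shared ** 2) / peak
    shared = shared - shared.mean()

    ap_clean = eff.amp_scale * shared
    smooth = np.convolve(ap_clean, [0.2, 0.6, 0.2], mode="same")
    f1 = rng.uniform(8.0, 14.0)
    indep = eff.amp_scale * env * np.sin(2 * np.pi * f1 * t + ph2)
    si_clean = coupling * smooth + (1.0 - coupling) * indep

    sigma = profile.noise_amplitude * eff.noise_scale
    rms_ap = np.sqrt(np.mean(ap_clean ** 2))
    rms_si = np.sqrt(np.mean(si_clean ** 2)) or rms_ap
    ap = ap_clean + sigma * rms_ap * rng.standard_normal(n)
    si = si_clean + sigma * rms_si * rng.standard_normal(n)
    return ap, si, d


# ---------------------------------------------------------------------------
# acquisition chain
# ---------------------------------------------------------------------------

def apply_acquisition(raw: np.ndarray, model: AcquisitionModel,
                      sampling_rate: float,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Pass samples through the simulated acquisition chain.

    output = gain * bandpass(AR_coloration(raw + sensor_noise)); length is
    preserved. With ``sensor_noise_sd=0`` the chain is purely linear.
    """
    model.validate(sampling_rate)
    x = np.asarray(raw, dtype=float)
    if model.sensor_noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when sensor_noise_sd > 0")
        x = x + model.sensor_noise_sd * rng.standard_normal(len(x))
    a = np.asarray(model.coloration_ar_coeffs, dtype=float)
    if a.size:
        x = sps.lfilter([1.0], np.concatenate([[1.0], -a]), x)
    if model.band_low is not None:
        hi = model.effective_band_high(sampling_rate)
        sos = sps.butter(2, [model.band_low, hi], btype="bandpass",
                         fs=sampling_rate, output="sos")
        x = sps.sosfilt(sos, x)
    return model.gain * x


# ---------------------------------------------------------------------------
# sessions and datasets
# ---------------------------------------------------------------------------

def _participant_rng(config: SyntheticConfig, participant_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed, spawn_key=(participant_index,))
    return np.random.default_rng(ss)


def generate_session(config: SyntheticConfig, participant_index: int,
                     ) -> tuple[list[tuple[DualAxisRecording, GroundTruth]],
                                DualAxisRecording]:
    """Generate one participant's 17 sequence recordings (with ground-truth
    swallow boundaries) plus one noise-only baseline recording.

    Returns ``(recordings, baseline)`` where ``recordings`` is a list of
    ``(DualAxisRecording, GroundTruth)`` pairs.
    """
    fs = config.sampling_rate
    rng = _participant_rng(config, participant_index)
    pid = f"P{participant_index:02d}"
    eff = draw_participant_effects(config, rng)
    plan = default_session_plan(pid)

    recordings: list[tuple[DualAxisRecording, GroundTruth]] = []
    for stimulus, task, rep in plan.entries:
        profile = config.profiles[stimulus]
        gap_mean = config.gap_discrete_s if task == "discrete" else config.gap_sequential_s
        ap_parts: list[np.ndarray] = []
        si_parts: list[np.ndarray] = []
        boundaries: list[tuple[int, int]] = []
        durations: list[float] = []

        def rest(mean_s: float, jitter: float) -> np.ndarray:
            length = max(1, int(round(max(0.05 * mean_s,
                                          mean_s + jitter * rng.standard_normal()) * fs)))
            return np.zeros(length)

        lead = rest(config.lead_in_s, 0.1 * config.lead_in_s)
        ap_parts.append(lead)
        si_parts.append(lead.copy())
        pos = len(lead)
        for k in range(4):
            ap_s, si_s, d = generate_swallow(
                profile, task, rng, sampling_rate=fs, coupling=config.coupling,
                effects=eff, within_sd=config.within_sd_duration)
            ap_parts.append(ap_s)
            si_parts.append(si_s)
            boundaries.append((pos, pos + len(ap_s)))
            durations.append(d)
            pos += len(ap_s)
            gap = rest(gap_mean, 0.15 * gap_mean) if k < 3 else rest(config.tail_s, 0.1 * config.tail_s)
            ap_parts.append(gap)
            si_parts.append(gap.copy())
            pos += len(gap)

        ap = np.concatenate(ap_parts)
        si = np.concatenate(si_parts)
        ap = apply_acquisition(ap, config.acquisition, fs, rng)
        si = apply_acquisition(si, config.acquisition, fs, rng)
        meta = RecordingMeta(pid, stimulus, task, rep, fs, baseline=False)
        rec = DualAxisRecording(ap, si, fs, meta)
        gt = GroundTruth(boundaries, durations, profile.noise_amplitude)
        gt.validate(rec.n)
        recordings.append((rec, gt))

    n_base = max(2, int(round(config.baseline_s * fs)))
    base_ap = apply_acquisition(np.zeros(n_base), config.acquisition, fs, rng)
    base_si = apply_acquisition(np.zeros(n_base), config.acquisition, fs, rng)
    baseline = DualAxisRecording(base_ap, base_si, fs,
                                 RecordingMeta(pid, "none", "none", 0, fs, baseline=True))
    return recordings, baseline


def generate_dataset(config: SyntheticConfig):
    """Yield ``(participant_id, recordings, baseline)`` for every participant."""
    for idx in range(config.n_participants):
        recordings, baseline = generate_session(config, idx)
        yield f"P{idx:02d}", recordings, baseline
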