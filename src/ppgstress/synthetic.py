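"""Synthetic PPG cohort generation.

Generates ground-truth NN-interval series and rendered pulse waveforms whose
statistical structure mimics a finger-PPG study protocol: seated rest and two
post-exercise states, 6-minute recordings sampled at 255 Hz.  Beat-to-beat
variability is modelled as a mean interval plus sinusoidal respiratory
(~0.25 Hz) and low-frequency (~0.1 Hz) modulation plus Gaussian jitter; the
waveform is a pulse-shaped template train with baseline wander, white noise
and optional transient artifact spikes.  Exercise states have shorter mean
intervals and less modulation, so their interval histograms are narrower and
taller and their Baevsky stress index is higher.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocessing import PPGRecording

__all__ = [
    "PhysioState",
    "SynthConfig",
    "GroundTruth",
    "REST",
    "EXERCISE_2SET",
    "EXERCISE_4SET",
    "DEFAULT_STATES",
    "generate_nni_series",
    "render_ppg",
    "generate_cohort",
]

_STATE_NAMES = ("rest", "exercise_2set", "exercise_4set")

# Physiological plausibility bounds: 60-180 bpm.
_MEAN_RR_MIN_MS = 330.0
_MEAN_RR_MAX_MS = 1500.0


@dataclass(frozen=True)
class PhysioState:
    """Parameters of one physiological state's beat-interval process.

    ``mean_rr`` is the mean beat interval in ms; ``rr_jitter_sd`` the SD of
    white Gaussian beat-to-beat jitter (ms); the two (amp, freq) pairs set
    sinusoidal respiratory and low-frequency interval modulation (ms, Hz).
    """

    name: str
    mean_rr: float
    rr_jitter_sd: float = 0.0
    resp_mod_amp: float = 0.0
    resp_mod_freq: float = 0.25
    lf_mod_amp: float = 0.0
    lf_mod_freq: float = 0.1

    def __post_init__(self) -> None:
        if self.name not in _STATE_NAMES:
            raise ValueError(f"state name must be one of {_STATE_NAMES}, got {self.name!r}")
        if not (_MEAN_RR_MIN_MS <= self.mean_rr <= _MEAN_RR_MAX_MS):
            raise ValueError(
                f"mean_rr must lie in [{_MEAN_RR_MIN_MS}, {_MEAN_RR_MAX_MS}] ms "
                f"(60-180 bpm), got {self.mean_rr}"
            )
        for attr in ("rr_jitter_sd", "resp_mod_amp", "resp_mod_freq", "lf_mod_amp", "lf_mod_freq"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")

    @property
    def total_modulation(self) -> float:
        """RMS beat-interval variability implied by the model (ms).

        Closed form: sqrt(jitter^2 + resp_amp^2/2 + lf_amp^2/2) -- each
        sinusoid contributes amp^2/2 to the interval variance.
        """
        return float(
            np.sqrt(
                self.rr_jitter_sd**2
                + self.resp_mod_amp**2 / 2.0
                + self.lf_mod_amp**2 / 2.0
            )
        )


# Default cohort states.  Rest at 850 ms (~71 bpm) with pronounced respiratory
# sinus arrhythmia; post-exercise states are faster with shrinking variability,
# bounded by the ~158 bpm extreme a push-up protocol can reach.
REST = PhysioState(
    name="rest", mean_rr=850.0, rr_jitter_sd=30.0,
    resp_mod_amp=40.0, resp_mod_freq=0.25, lf_mod_amp=25.0, lf_mod_freq=0.1,
)
EXERCISE_2SET = PhysioState(
    name="exercise_2set", mean_rr=650.0, rr_jitter_sd=12.0,
    resp_mod_amp=15.0, resp_mod_freq=0.30, lf_mod_amp=8.0, lf_mod_freq=0.1,
)
EXERCISE_4SET = PhysioState(
    name="exercise_4set", mean_rr=520.0, rr_jitter_sd=6.0,
    resp_mod_amp=7.0, resp_mod_freq=0.35, lf_mod_amp=4.0, lf_mod_freq=0.1,
)
DEFAULT_STATES = (REST, EXERCISE_2SET, EXERCISE_4SET)


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-level simulation configuration.

    Defaults emulate the study protocol: 17 subjects, three states, 6-minute
    recordings at 255 Hz.  ``duration_s`` must leave at least one 60 s label
    window after the 30 s + 30 s head/tail trim.
    """

    states: tuple[PhysioState, ...] = DEFAULT_STATES
    n_subjects: int = 17
    duration_s: float = 360.0
    fs: float = 255.0
    noise_sd: float = 0.03
    baseline_amp: float = 0.25
    baseline_freq: float = 0.2
    artifact_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.duration_s < 120.0:
            raise ValueError("duration_s must be >= 120 s (30 s + 30 s trim + one 60 s window)")
        if self.fs < 6.0:
            raise ValueError("fs must be >= 6 Hz (twice the 3.0 Hz band edge)")
        if not self.states:
            raise ValueError("states must be non-empty")


@dataclass(frozen=True)
class GroundTruth:
    """True pulse times (s) and beat intervals (ms) of a simulated recording."""

    pulse_times: np.ndarray
    rr_intervals: np.ndarray
    state: PhysioState

    def __post_init__(self) -> None:
        if np.any(self.rr_intervals <= 0):
            raise ValueError("rr_intervals must be strictly positive")


def generate_nni_series(state: PhysioState, duration_s: float, seed: int) -> GroundTruth:
    """Simulate a beat-interval series for one recording.

    Each interval is ``mean_rr + resp_mod + lf_mod + jitter`` evaluated at the
    beat's onset time; modulation phases are randomized per recording so
    analysis windows are not phase-locked.  Pulse times accumulate until they
    cover ``duration_s``.  Deterministic for a fixed seed.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    resp_phase = rng.uniform(0, 2 * np.pi)
    lf_phase = rng.uniform(0, 2 * np.pi)

    times = [0.0]
    intervals = []
    t = 0.0
    while t < duration_s:
        rr = (
            state.mean_rr
            + state.resp_mod_amp * np.sin(2 * np.pi * state.resp_mod_freq * t + resp_phase)
            + state.lf_mod_amp * np.sin(2 * np.pi * state.lf_mod_freq * t + lf_phase)
            + rng.normal(0.0, state.rr_jitter_sd)
        )
        if rr <= 0:
            raise ValueError(
                "state parameters produced a non-positive beat interval; "
                "reduce modulation/jitter relative to mean_rr"
            )
        t += rr / 1000.0
        times.append(t)
        intervals.append(rr)
    return GroundTruth(
        pulse_times=np.asarray(times),
        rr_intervals=np.asarray(intervals),
        state=state,
    )


# Pulse template: systolic Gaussian peak plus a smaller, broader dicrotic bump.
# Only the peak *times* matter downstream; the systolic width is chosen so
# that after a 0.5-3.0 Hz band-pass each beat still presents a single
# dominant local maximum at the systolic peak (a narrower peak leaves too
# much second-harmonic energy in-band at resting heart rates, which splits
# beats in two).
_SYSTOLIC_SD_S = 0.090
_DICROTIC_DELAY_S = 0.300
_DICROTIC_SD_S = 0.100
_DICROTIC_AMP = 0.30
_ARTIFACT_AMP = 3.0
_ARTIFACT_SD_S = 0.030


def _template(dt: np.ndarray) -> np.ndarray:
    """Pulse waveform at offsets ``dt`` (s) from the beat's systolic peak."""
    systolic = np.exp(-0.5 * (dt / _SYSTOLIC_SD_S) ** 2)
    dicrotic = _DICROTIC_AMP * np.exp(-0.5 * ((dt - _DICROTIC_DELAY_S) / _DICROTIC_SD_S) ** 2)
    return systolic + dicrotic


def render_ppg(
    truth: GroundTruth,
    fs: float = 255.0,
    noise_sd: float = 0.0,
    baseline_amp: float = 0.0,
    baseline_freq: float = 0.2,
    artifact_rate: float = 0.0,
    seed: int = 0,
    subject_id: str = "synthetic",
    duration_s: float | None = None,
) -> PPGRecording:
    """Render a sampled PPG waveform from ground-truth pulse times.

    The waveform is the sum of pulse templates centered at each pulse time,
    plus sinusoidal baseline wander, white Gaussian noise and -- at Poisson
    times with rate ``artifact_rate`` per minute -- transient amplitude
    spikes emulating motion artifacts.
    """
    if fs < 6.0:
        raise ValueError("fs must be >= 6 Hz")
    rng = np.random.default_rng(seed)
    if duration_s is None:
        duration = float(truth.pulse_times[-1])
        n = int(np.floor(duration * fs)) + 1
    else:
        duration = float(duration_s)
        n = int(round(duration * fs))
    t = np.arange(n) / fs

    x = np.zeros(n)
    half_width = _DICROTIC_DELAY_S + 5 * _DICROTIC_SD_S
    for pt in truth.pulse_times:
        lo = max(0, int(np.ceil((pt - 5 * _SYSTOLIC_SD_S - half_width) * fs)))
        hi = min(n, int(np.floor((pt + half_width) * fs)) + 1)
        if lo < hi:
            x[lo:hi] += _template(t[lo:hi] - pt)

    if baseline_amp > 0:
        baseline_phase = rng.uniform(0, 2 * np.pi)
        x += baseline_amp * np.sin(2 * np.pi * baseline_freq * t + baseline_phase)
    if artifact_rate > 0:
        n_artifacts = rng.poisson(artifact_rate * duration / 60.0)
        artifact_times = rng.uniform(0, duration, size=n_artifacts)
        for at in artifact_times:
            x += _ARTIFACT_AMP * np.exp(-0.5 * ((t - at) / _ARTIFACT_SD_S) ** 2)
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n)

    return PPGRecording(
        samples=x, fs=fs, subject_id=subject_id, state=truth.state.name, t0=0.0
    )


def _perturb_state(state: PhysioState, rng: np.random.Generator) -> PhysioState:
    """Per-subject parameter perturbation: ~5% multiplicative scatter."""
    def jig(x: float, frac: float = 0.05) -> float:
        return float(x * (1.0 + frac * rng.standard_normal())) if x > 0 else x

    mean_rr = float(np.clip(jig(state.mean_rr), _MEAN_RR_MIN_MS, _MEAN_RR_MAX_MS))
    return replace(
        state,
        mean_rr=mean_rr,
        rr_jitter_sd=abs(jig(state.rr_jitter_sd)),
        resp_mod_amp=abs(jig(state.resp_mod_amp)),
        lf_mod_amp=abs(jig(state.lf_mod_amp)),
    )


def generate_cohort(config: SynthConfig) -> list[tuple[PPGRecording, GroundTruth]]:
    """Generate ``n_subjects x len(states)`` recordings with ground truth.

    Per-subject state parameters are perturbed from the configured state
    templates by a seeded generator, so subjects differ but the cohort is
    fully reproducible from ``config.seed``.
    """
    master = np.random.default_rng(config.seed)
    out: list[tuple[PPGRecording, GroundTruth]] = []
    for subj in range(config.n_subjects):
        for state in config.states:
            pstate = _perturb_state(state, master)
            nni_seed = int(master.integers(0, 2**31 - 1))
            render_seed = int(master.integers(0, 2**31 - 1))
            truth = generate_nni_series(pstate, config.duration_s, nni_seed)
            rec = render_ppg(
                truth,
                fs=config.fs,
                noise_sd=config.noise_sd,
                baseline_amp=config.baseline_amp,
                baseline_freq=config.baseline_freq,
                artifact_rate=config.artifact_rate,
                seed=render_seed,
                subject_id=f"subject{subj}",
                duration_s=config.duration_s,
            )
            out.append((rec, truth))
    return out
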