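"""Raw PPG waveform to clean NN-interval series.

Pipeline: discard the noisy head and tail of the recording, band-pass to the
pulse band (0.5-3.0 Hz, i.e. 30-180 bpm), detect systolic peaks, take
peak-to-peak intervals (PPI, ms), remove z-score outlier intervals at a
threshold T, and replace each removed interval with the median of its two
nearest surviving neighbours to obtain the NN-interval (NNI) series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "PPGRecording",
    "PPISeries",
    "NNISeries",
    "PreprocessConfig",
    "trim_recording",
    "bandpass",
    "detect_peaks",
    "remove_outlier_ppi",
    "replace_removed",
    "preprocess",
]


class InsufficientDataError(ValueError):
    """Raised when a series is too short or degenerate for an operation."""


@dataclass(frozen=True)
class PPGRecording:
    """A sampled PPG waveform.

    ``t0`` is the absolute time (s) of the first sample, so trimmed
    recordings keep track of their offset into the original signal.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    state: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.size < 2:
            raise ValueError("recording must contain at least 2 samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class PPISeries:
    """Peak-to-peak intervals with per-interval outlier mask.

    ``intervals[i]`` is ``(peak_times[i+1] - peak_times[i]) * 1000`` ms.
    ``removal_mask[i]`` marks intervals flagged for replacement.
    """

    peak_times: np.ndarray
    intervals: np.ndarray
    removal_mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "peak_times", np.asarray(self.peak_times, dtype=float))
        object.__setattr__(self, "intervals", np.asarray(self.intervals, dtype=float))
        object.__setattr__(self, "removal_mask", np.asarray(self.removal_mask, dtype=bool))
        if self.intervals.size != self.peak_times.size - 1:
            raise ValueError("need exactly one interval per successive peak pair")
        if self.removal_mask.size != self.intervals.size:
            raise ValueError("removal_mask must match intervals in length")
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be strictly positive")


@dataclass(frozen=True)
class NNISeries:
    """Normal-to-normal intervals in ms after outlier replacement.

    ``replaced[i]`` is True where the original PPI was removed and filled in.
    ``start_time`` is the absolute time (s) of the first interval's opening
    beat.  ``t0`` and ``duration_s``, when known, give the start and span of
    the source recording and anchor analysis windows.
    """

    intervals: np.ndarray
    replaced: np.ndarray
    start_time: float = 0.0
    t0: float = 0.0
    duration_s: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", np.asarray(self.intervals, dtype=float))
        object.__setattr__(self, "replaced", np.asarray(self.replaced, dtype=bool))
        if self.replaced.size != self.intervals.size:
            raise ValueError("replaced must match intervals in length")
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be strictly positive")

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def end_times(self) -> np.ndarray:
        """Absolute time (s) of each interval's closing beat."""
        return self.start_time + np.cumsum(self.intervals) / 1000.0


@dataclass(frozen=True)
class PreprocessConfig:
    trim_head_s: float = 30.0
    trim_tail_s: float = 30.0
    band_low: float = 0.5
    band_high: float = 3.0
    z_threshold: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError("need 0 < band_low < band_high")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.trim_head_s < 0 or self.trim_tail_s < 0:
            raise ValueError("trim durations must be non-negative")


def trim_recording(rec: PPGRecording, head_s: float = 30.0, tail_s: float = 30.0) -> PPGRecording:
    """Drop the first ``head_s`` and last ``tail_s`` seconds of a recording."""
    if rec.duration_s <= head_s + tail_s:
        raise InsufficientDataError(
            f"recording of {rec.duration_s:.1f} s cannot be trimmed by "
            f"{head_s} + {tail_s} s"
        )
    lo = int(round(head_s * rec.fs))
    hi = rec.samples.size - int(round(tail_s * rec.fs))
    return PPGRecording(
        samples=rec.samples[lo:hi],
        fs=rec.fs,
        subject_id=rec.subject_id,
        state=rec.state,
        t0=rec.t0 + head_s,
    )


def bandpass(rec: PPGRecording, low: float = 0.5, high: float = 3.0) -> PPGRecording:
    """Zero-phase 4th-order Butterworth band-pass.

    Forward-backward filtering keeps peak timing unshifted, which is the
    quantity the rest of the pipeline depends on.
    """
    nyq = rec.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz must lie inside (0, {nyq}) Hz")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return PPGRecording(
        samples=filtered, fs=rec.fs, subject_id=rec.subject_id, state=rec.state, t0=rec.t0
    )


def detect_peaks(rec: PPGRecording, max_hr_hz: float = 3.0, prominence_sd: float = 0.3) -> PPISeries:
    """Detect systolic peaks and return peak-to-peak intervals.

    Local-maxima detection with a minimum inter-peak distance of
    ``fs / max_hr_hz`` samples (the filter's 3.0 Hz band edge implies at most
    180 bpm) and a prominence floor of ``prominence_sd`` times the signal SD.
    Peak locations are refined to sub-sample precision by fitting a parabola
    through the three samples around each local maximum, so interval accuracy
    is not limited to the sample grid.
    """
    sd = float(np.std(rec.samples))
    if sd == 0:
        raise InsufficientDataError("flat signal: no peaks")
    distance = max(1, int(np.floor(rec.fs / max_hr_hz)))
    peaks, _ = signal.find_peaks(rec.samples, distance=distance, prominence=prominence_sd * sd)
    if peaks.size < 2:
        raise InsufficientDataError(f"found {peaks.size} peaks; need at least 2")
    refined = peaks.astype(float)
    interior = (peaks > 0) & (peaks < rec.samples.size - 1)
    y0 = rec.samples[peaks[interior] - 1]
    y1 = rec.samples[peaks[interior]]
    y2 = rec.samples[peaks[interior] + 1]
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = np.where(denom != 0, 0.5 * (y0 - y2) / denom, 0.0)
    refined[interior] += np.clip(shift, -0.5, 0.5)
    peak_times = rec.t0 + refined / rec.fs
    intervals = np.diff(peak_times) * 1000.0
    return PPISeries(
        peak_times=peak_times,
        intervals=intervals,
        removal_mask=np.zeros(intervals.size, dtype=bool),
    )


def remove_outlier_ppi(ppi: PPISeries, T: float = 2.0) -> PPISeries:
    """Flag intervals whose |z-score| >= T for replacement.

    The z-score uses the mean and population SD (ddof 0) of the full series,
    computed once -- removal is a single pass, not iterative.  A zero-SD
    (constant) series is a no-op.
    """
    if ppi.intervals.size < 3:
        raise InsufficientDataError("need at least 3 intervals for outlier screening")
    sd = float(np.std(ppi.intervals))
    if sd == 0:
        mask = np.zeros(ppi.intervals.size, dtype=bool)
    else:
        z = np.abs(ppi.intervals - np.mean(ppi.intervals)) / sd
        mask = z >= T
    if mask.all():
        raise InsufficientDataError("every interval flagged as an outlier")
    return PPISeries(peak_times=ppi.peak_times, intervals=ppi.intervals, removal_mask=mask)


def replace_removed(ppi: PPISeries) -> NNISeries:
    """Replace flagged intervals to produce the NNI series.

    Each flagged interval becomes the median of its nearest surviving
    neighbours on either side (the median of two values is their mean); a
    flagged interval at the boundary, with survivors on one side only, copies
    the single nearest survivor.  Runs of consecutive flags all use the run's
    flanking survivors.  Interval count is preserved.
    """
    mask = ppi.removal_mask
    if mask.all():
        raise InsufficientDataError("every interval removed; nothing to interpolate from")
    intervals = ppi.intervals.copy()
    surviving = np.flatnonzero(~mask)
    for i in np.flatnonzero(mask):
        prev_candidates = surviving[surviving < i]
        next_candidates = surviving[surviving > i]
        neighbours = []
        if prev_candidates.size:
            neighbours.append(intervals[prev_candidates[-1]])
        if next_candidates.size:
            neighbours.append(intervals[next_candidates[0]])
        intervals[i] = float(np.median(neighbours))
    return NNISeries(
        intervals=intervals,
        replaced=mask.copy(),
        start_time=float(ppi.peak_times[0]),
    )


def preprocess(rec: PPGRecording, cfg: PreprocessConfig = PreprocessConfig()) -> NNISeries:
    """Full pipeline: trim -> band-pass -> peaks -> outlier removal -> NNI."""
    trimmed = trim_recording(rec, cfg.trim_head_s, cfg.trim_tail_s)
    filtered = bandpass(trimmed, cfg.band_low, cfg.band_high)
    ppi = detect_peaks(filtered, max_hr_hz=cfg.band_high)
    ppi = remove_outlier_ppi(ppi, cfg.z_threshold)
    nni = replace_removed(ppi)
    return NNISeries(
        intervals=nni.intervals,
        replaced=nni.replaced,
        start_time=nni.start_time,
        t0=trimmed.t0,
        duration_s=trimmed.duration_s,
    )
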