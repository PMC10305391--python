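"""Windowed regression dataset construction.

From each recording's NN-interval series, windows of length L seconds are
slid at a 1 s stride.  A sample's input features are the time-domain PRV
features of the NNIs inside ``[t_start, t_start + L)``; its label is the
square root of the Baevsky stress index of the NNIs in the 60 s starting at
the same instant, ``[t_start, t_start + 60 s)``.  Window starts run from the
recording origin up to ``duration - 60 s``, so the per-recording sample
count -- and the label sequence -- is identical for every L: differences in
downstream regression accuracy are attributable to the features alone.

Features whose short-window values agree poorly with the same feature
computed on the full recording (agreement R-squared below 0.6 against the
5-minute reference) are discarded, and the surviving feature rows are scaled
to unit L2 norm before modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import Normalizer

from .features import FEATURE_NAMES, PRVFeatureVector, compute_features
from .preprocessing import InsufficientDataError, NNISeries
from .stress import DegenerateSpreadError, compute_si

__all__ = [
    "WindowSample",
    "FeatureSelectionReport",
    "Dataset",
    "EmptySelectionError",
    "slide_windows",
    "feature_reference_r2",
    "select_features",
    "scale_features",
    "build_dataset",
]

logger = logging.getLogger(__name__)

LABEL_LEN_S = 60.0
R2_THRESHOLD = 0.6


class EmptySelectionError(ValueError):
    """No feature met the agreement threshold."""


@dataclass(frozen=True)
class WindowSample:
    recording_id: str
    t_start: float
    window_len: float
    features: PRVFeatureVector
    label: float


@dataclass(frozen=True)
class FeatureSelectionReport:
    """Per-feature agreement R-squared against the full-length reference.

    ``r2`` maps feature name to the coefficient of determination obtained by
    treating each recording's full-length feature value as the target and the
    short-window value as the prediction; it can be negative, and is NaN when
    the reference values have zero variance (agreement undefined).
    """

    r2: dict[str, float]
    threshold: float
    window_len: float

    @property
    def selected(self) -> tuple[str, ...]:
        return tuple(n for n in self.r2 if self.r2[n] >= self.threshold)


@dataclass(frozen=True)
class Dataset:
    """Model-ready samples for one window length."""

    samples: tuple[WindowSample, ...]
    selected_features: tuple[str, ...]
    scaled_matrix: np.ndarray
    window_len: float

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples])

    @property
    def groups(self) -> np.ndarray:
        """Recording id per sample, for leakage-free grouped CV."""
        return np.array([s.recording_id for s in self.samples])

    def __len__(self) -> int:
        return len(self.samples)


def _segment(nni: NNISeries, t_start: float, length: float) -> np.ndarray:
    """Intervals whose ending beat time falls in [t_start, t_start + length)."""
    end = nni.end_times
    sel = (end >= t_start) & (end < t_start + length)
    return nni.intervals[sel]


def slide_windows(
    nni: NNISeries,
    L: float,
    stride: float = 1.0,
    label_len: float = LABEL_LEN_S,
    recording_id: str = "",
) -> list[WindowSample]:
    """Slide L-second feature windows at ``stride`` over one recording.

    An interval belongs to the window containing its *ending* beat.  Windows
    with fewer than 3 intervals, or whose 60 s label segment is degenerate
    (all intervals identical), are dropped and counted in the log.
    """
    if L > label_len:
        raise ValueError(f"window length {L} s exceeds label length {label_len} s")
    if nni.duration_s is None:
        duration = float(nni.end_times[-1] - nni.t0)
    else:
        duration = float(nni.duration_s)
    if duration < label_len:
        raise InsufficientDataError(
            f"recording spans {duration:.1f} s; need >= {label_len} s for the label"
        )

    samples: list[WindowSample] = []
    dropped = 0
    n_starts = int(np.floor((duration - label_len) / stride)) + 1
    for k in range(n_starts):
        t_start = nni.t0 + k * stride
        window = _segment(nni, t_start, L)
        label_seg = _segment(nni, t_start, label_len)
        try:
            feats = compute_features(window)
            label = compute_si(label_seg).sqrt_si
        except (InsufficientDataError, DegenerateSpreadError):
            dropped += 1
            continue
        samples.append(
            WindowSample(
                recording_id=recording_id,
                t_start=t_start,
                window_len=L,
                features=feats,
                label=label,
            )
        )
    if dropped:
        logger.info(
            "recording %s, L=%gs: dropped %d of %d windows (too few beats or degenerate label)",
            recording_id, L, dropped, n_starts,
        )
    return samples


def feature_reference_r2(
    samples: list[WindowSample],
    reference: dict[str, PRVFeatureVector],
    threshold: float = R2_THRESHOLD,
) -> FeatureSelectionReport:
    """Agreement R-squared of each short-window feature with its reference.

    Each sample is paired with its source recording's full-length feature
    vector; for feature f,

        R2(f) = 1 - sum_i (ref_i - short_i)^2 / sum_i (ref_i - mean(ref))^2.

    Zero variance in the reference values leaves that feature's R2 undefined
    (NaN), so it can never be selected.
    """
    if not samples:
        raise InsufficientDataError("no samples")
    missing = {s.recording_id for s in samples} - set(reference)
    if missing:
        raise KeyError(f"no reference features for recordings {sorted(missing)}")
    window_len = samples[0].window_len

    r2: dict[str, float] = {}
    for name in FEATURE_NAMES:
        ref = np.array([getattr(reference[s.recording_id], name) for s in samples], dtype=float)
        short = np.array([getattr(s.features, name) for s in samples], dtype=float)
        ss_tot = float(np.sum((ref - ref.mean()) ** 2))
        if ss_tot == 0:
            r2[name] = float("nan")
            continue
        r2[name] = 1.0 - float(np.sum((ref - short) ** 2)) / ss_tot
    return FeatureSelectionReport(r2=r2, threshold=threshold, window_len=window_len)


def select_features(report: FeatureSelectionReport, threshold: float | None = None) -> tuple[str, ...]:
    """Names of features with agreement R2 >= threshold, in stable order."""
    thr = report.threshold if threshold is None else threshold
    selected = tuple(n for n in report.r2 if report.r2[n] >= thr)
    if not selected:
        raise EmptySelectionError(f"no feature reached R2 >= {thr}")
    return selected


def scale_features(matrix: np.ndarray) -> np.ndarray:
    """Scale each sample row to unit L2 norm (the 'normalizer' scaler)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("expected a 2-D samples x features matrix")
    norms = np.linalg.norm(matrix, axis=1)
    if np.any(norms == 0):
        raise ValueError("cannot scale an all-zero feature row")
    return Normalizer(norm="l2").fit_transform(matrix)


def build_dataset(
    nnis: dict[str, NNISeries],
    L: float,
    stride: float = 1.0,
    label_len: float = LABEL_LEN_S,
    threshold: float = R2_THRESHOLD,
) -> tuple[Dataset, FeatureSelectionReport]:
    """Assemble the model-ready dataset for one window length.

    Slides windows over every recording, computes the full-length reference
    features per recording, selects features by agreement R2 >= threshold on
    the pooled samples, and unit-norm scales the selected columns.
    """
    samples: list[WindowSample] = []
    reference: dict[str, PRVFeatureVector] = {}
    for rec_id, nni in nnis.items():
        reference[rec_id] = compute_features(nni)
        samples.extend(slide_windows(nni, L, stride, label_len, recording_id=rec_id))
    if not samples:
        raise InsufficientDataError("no usable windows in any recording")
    report = feature_reference_r2(samples, reference, threshold)
    selected = select_features(report)
    raw = np.array([s.features.as_array(selected) for s in samples])
    scaled = scale_features(raw)
    return (
        Dataset(
            samples=tuple(samples),
            selected_features=selected,
            scaled_matrix=scaled,
            window_len=L,
        ),
        report,
    )
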