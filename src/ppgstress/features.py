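"""Time-domain pulse-rate-variability features.

The 18 standard time-domain indices computed from an NN-interval segment:
interval statistics (mean/median/min/max/range, SDNN), successive-difference
statistics (SDSD, RMSSD, NNI50/pNNI50, NNI20/pNNI20), coefficients of
variation (CVSD, CVNNI), and per-beat instantaneous heart-rate statistics.

Conventions (fixed, documented in docs/methods.md):

* SDNN, SDSD and Std HR use the sample SD (ddof 1).
* NNI50 / NNI20 count successive differences strictly greater than 50 / 20 ms
  in absolute value; pNNI50 / pNNI20 divide by the number of intervals and
  are reported as proportions in [0, 1].
* Heart-rate statistics are computed on the per-beat instantaneous rate
  60000 / nn_i (bpm), not on 60000 / mean(nn).
* Median NNI is the median of the intervals themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .preprocessing import InsufficientDataError, NNISeries

__all__ = ["PRVFeatureVector", "FEATURE_NAMES", "compute_features"]


@dataclass(frozen=True)
class PRVFeatureVector:
    mean_nni: float
    sdnn: float
    sdsd: float
    rmssd: float
    median_nni: float
    nni_50: int
    pnni_50: float
    nni_20: int
    pnni_20: float
    range_nni: float
    cvsd: float
    cvnni: float
    mean_hr: float
    max_hr: float
    min_hr: float
    std_hr: float
    max_nni: float
    min_nni: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_array(self, names: list[str] | tuple[str, ...] | None = None) -> np.ndarray:
        names = FEATURE_NAMES if names is None else names
        return np.array([getattr(self, n) for n in names], dtype=float)


FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in fields(PRVFeatureVector))


def compute_features(nni: NNISeries | np.ndarray) -> PRVFeatureVector:
    """Compute all 18 time-domain PRV features from an NNI segment.

    Accepts an :class:`NNISeries` or a plain array of intervals in ms.
    Requires at least 3 intervals so that successive differences and sample
    standard deviations are defined.
    """
    x = nni.intervals if isinstance(nni, NNISeries) else np.asarray(nni, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 intervals, got {x.size}")
    diffs = np.diff(x)
    hr = 60000.0 / x

    mean_nni = float(np.mean(x))
    sdnn = float(np.std(x, ddof=1))
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    nni_50 = int(np.sum(np.abs(diffs) > 50.0))
    nni_20 = int(np.sum(np.abs(diffs) > 20.0))
    return PRVFeatureVector(
        mean_nni=mean_nni,
        sdnn=sdnn,
        sdsd=float(np.std(diffs, ddof=1)),
        rmssd=rmssd,
        median_nni=float(np.median(x)),
        nni_50=nni_50,
        pnni_50=nni_50 / x.size,
        nni_20=nni_20,
        pnni_20=nni_20 / x.size,
        range_nni=float(np.max(x) - np.min(x)),
        cvsd=rmssd / mean_nni,
        cvnni=sdnn / mean_nni,
        mean_hr=float(np.mean(hr)),
        max_hr=float(np.max(hr)),
        min_hr=float(np.min(hr)),
        std_hr=float(np.std(hr, ddof=1)),
        max_nni=float(np.max(x)),
        min_nni=float(np.min(x)),
    )
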