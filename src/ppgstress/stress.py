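"""Baevsky stress index from an NN-interval segment.

    SI = AMo[%] / (2 * Mo[s] * MxDMn[s])

where the NNI histogram uses fixed-width bins (default 50 ms) anchored at
0 ms; Mo (mode) is the modal bin's midpoint in seconds; AMo (amplitude of
mode) is the percentage of intervals falling in the modal bin; and MxDMn is
the range max(NNI) - min(NNI) in seconds.  A narrow, tall interval histogram
(sympathetic activation) drives SI up; the normal relaxed range is roughly
80-150.  The square root of SI is used downstream as the regression label to
damp the influence of extreme values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import InsufficientDataError, NNISeries

__all__ = ["StressIndexResult", "DegenerateSpreadError", "compute_si"]


class DegenerateSpreadError(ValueError):
    """All intervals identical: MxDMn = 0 and the index is undefined."""


@dataclass(frozen=True)
class StressIndexResult:
    mo: float           # modal-bin midpoint, s
    amo: float          # % of intervals in the modal bin
    mx: float           # longest NNI, s
    mn: float           # shortest NNI, s
    mxdmn: float        # mx - mn, s
    si: float
    sqrt_si: float
    bin_width: float    # ms


def compute_si(nni: NNISeries | np.ndarray, bin_width: float = 50.0) -> StressIndexResult:
    """Compute the Baevsky stress index and its square root.

    Histogram bins are ``[k*w, (k+1)*w)`` ms anchored at 0; modal-bin ties
    break toward the lower bin so the result is deterministic.  Mx and Mn are
    taken from the raw intervals, not bin edges.  Raises
    :class:`DegenerateSpreadError` when all intervals are identical.
    """
    x = nni.intervals if isinstance(nni, NNISeries) else np.asarray(nni, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"need >= 2 intervals, got {x.size}")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    mx = float(np.max(x)) / 1000.0
    mn = float(np.min(x)) / 1000.0
    mxdmn = mx - mn
    if mxdmn == 0:
        raise DegenerateSpreadError("all intervals identical (MxDMn = 0); SI undefined")

    bin_idx = np.floor(x / bin_width).astype(np.int64)
    counts = np.bincount(bin_idx - bin_idx.min())
    modal = int(np.argmax(counts))  # argmax takes the first (lowest) bin on ties
    modal_bin = modal + int(bin_idx.min())
    mo = (modal_bin + 0.5) * bin_width / 1000.0
    amo = 100.0 * counts[modal] / x.size

    si = amo / (2.0 * mo * mxdmn)
    return StressIndexResult(
        mo=mo, amo=amo, mx=mx, mn=mn, mxdmn=mxdmn,
        si=si, sqrt_si=float(np.sqrt(si)), bin_width=bin_width,
    )
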