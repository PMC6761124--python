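"""Centred rolling statistics shared by the normalisation steps.

Both the methylation-heterogeneity and the expression-variability
normalisations remove a running trend by subtracting a centred rolling
statistic computed over records ordered by a covariate (mean methylation,
mean expression).  Edge windows shrink symmetrically down to a minimum
half-width so edge records are kept rather than discarded.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["rolling_centered", "sliding_zscore"]


def rolling_centered(
    values: np.ndarray,
    window: int,
    stat: Callable[[np.ndarray], float],
    min_half: int | None = None,
) -> np.ndarray:
    """Apply ``stat`` over a centred window of ~``window`` observations.

    The half-width is ``window // 2``.  Near the ends the window shrinks
    symmetrically, but never below ``min_half`` on the long side (it is then
    truncated at the array bounds), so edge estimates still pool a sensible
    number of neighbours.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    h = max(1, window // 2)
    if min_half is None:
        min_half = h
    out = np.empty(n)
    for i in range(n):
        hw = min(h, i, n - 1 - i)
        hw = max(hw, min(min_half, h))
        lo = max(0, i - hw)
        hi = min(n, i + hw + 1)
        out[i] = stat(values[lo:hi])
    return out


def sliding_zscore(
    values: np.ndarray, order: np.ndarray, window: int = 100
) -> np.ndarray:
    """Z-score each value against a sliding window of its neighbours.

    Records are ordered by ``order``; each record is standardised against the
    mean and s.d. (ddof=1) of the ~``window`` observations centred on it.  A
    zero-variance window yields z = 0.  The result is returned in the
    original record order.
    """
    values = np.asarray(values, dtype=float)
    order = np.asarray(order, dtype=float)
    if values.shape != order.shape:
        raise ValueError("values and order must have equal length")
    idx = np.argsort(order, kind="stable")
    v = values[idx]
    n = v.size
    h = max(1, window // 2)
    z_sorted = np.empty(n)
    for i in range(n):
        lo = max(0, i - h)
        hi = min(n, i + h + 1)
        seg = v[lo:hi]
        mu = seg.mean()
        sd = seg.std(ddof=1) if seg.size > 1 else 0.0
        # a window whose spread is pure floating-point jitter counts as
        # zero-variance, matching the "all differences equal -> z = 0" rule
        if sd <= 1e-12 * max(1.0, abs(mu)):
            z_sorted[i] = 0.0
        else:
            z_sorted[i] = (v[i] - mu) / sd
    z = np.empty(n)
    z[idx] = z_sorted
    return z
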