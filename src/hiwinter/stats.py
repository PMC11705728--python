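"""Shared statistical helpers (multiple-testing adjustment)."""

from __future__ import annotations

import numpy as np

__all__ = ["bh_adjust"]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    ``q_(i) = min_{j >= i} (p_(j) * m / j)`` clipped at 1, where m counts
    the non-missing p-values. Missing entries (NaN) are skipped and
    returned as NaN; the original order is restored. Tied p-values share
    their adjusted value by construction.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-dimensional")
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    qv = np.empty(m)
    qv[order] = q
    out[ok] = qv
    return out
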