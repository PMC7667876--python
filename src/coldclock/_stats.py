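"""Small shared statistics helpers.

Multiple-testing corrections are written out explicitly because they are part
of the package's statistical contract (step-up Benjamini-Hochberg for the
differential tests, step-down Holm-Bonferroni for the circadian comparisons);
tests cross-check them against statsmodels.
"""
from __future__ import annotations

import numpy as np


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries (untested hypotheses) are excluded from the family and
    returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    adj = np.full(p.shape, np.nan)
    tested = ~np.isnan(p)
    ps = p[tested]
    m = ps.size
    if m == 0:
        return adj
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    adj[tested] = out
    return adj


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * (m - np.arange(m))
    ranked = np.maximum.accumulate(ranked)
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out
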