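"""Shared statistical comparisons.

Condition contrasts throughout the pipeline use the two-sided Mann–Whitney
U test: exact for small samples without ties, normal approximation with tie
correction otherwise.
"""
from __future__ import annotations

import numpy as np
from scipy import stats as _st

__all__ = ["mann_whitney", "descriptives"]

_EXACT_MAX_N = 50


def mann_whitney(x, y, alternative: str = "two-sided"):
    """Two-sided (by default) Mann–Whitney U test.

    Returns ``(U, p)`` where U is the statistic for the first sample.  The
    exact null distribution is enumerated when both groups have fewer than
    50 observations and there are no ties; otherwise the normal
    approximation with tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if no_ties and x.size < _EXACT_MAX_N and y.size < _EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = _st.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def descriptives(values) -> dict:
    """Median, mean, SEM and IQR of a sample (NaNs dropped)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {"n": 0, "median": np.nan, "mean": np.nan, "sem": np.nan,
                "q1": np.nan, "q3": np.nan}
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    sem = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan
    return {"n": int(v.size), "median": float(med), "mean": float(v.mean()),
            "sem": float(sem), "q1": float(q1), "q3": float(q3)}
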