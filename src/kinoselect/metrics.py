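"""Comparison selectivity metrics: Gini coefficient and S(x) threshold scores.

These are the metrics the selectivity score is usually compared against.
Both operate on a compound's full profile of non-missing percent-inhibition
values across the panel (targets included).  The Gini coefficient here is
the population form without the n/(n-1) sample correction; output headers
label it as such since published variants differ.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


def _as_profile(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValidationError("a metric profile needs at least 2 measured values")
    if x.min() < 0 or x.max() > 100:
        raise ValidationError("profile values must lie in [0, 100]")
    return x


def gini_coefficient(values) -> float:
    """Gini inequality coefficient of an inhibition profile, in [0, 1].

    Gini = sum_ij |x_i - x_j| / (2 n^2 xbar).  0 means a perfectly uniform
    (promiscuous) profile; values near 1 mean inhibition concentrated on a
    few kinases.  An all-zero profile returns 0 by convention.  Computed via
    the sorted-rank identity, O(n log n); tests check it against the naive
    double loop.
    """
    x = _as_profile(values)
    total = x.sum()
    if total == 0.0:
        return 0.0
    n = x.size
    xs = np.sort(x)
    ranks = np.arange(1, n + 1)
    # identity: sum_ij |xi - xj| = 2 * sum_i (2i - n - 1) * x_(i)
    return float(np.sum((2 * ranks - n - 1) * xs) / (n * total))


def s_score(values, x: float) -> float:
    """S(x): fraction of profiled kinases inhibited at least ``x`` percent.

    ``x`` must lie in (0, 100].  This is the threshold-based comparator the
    smooth selectivity score avoids: a pan-weak compound (all inhibitions
    below x) is invisible to S(x).
    """
    x = float(x)
    if not (0.0 < x <= 100.0):
        raise ValidationError(f"S(x) threshold must lie in (0, 100], got {x}")
    profile = _as_profile(values)
    return float(np.mean(profile >= x))
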