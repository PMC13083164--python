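"""Small statistical utilities: McNemar's test, Holm step-down adjustment
and Monte-Carlo bootstrap p-values."""

from __future__ import annotations

import numpy as np
from scipy.stats import binom, chi2


def mcnemar_p(b: int, c: int, exact_below: int = 25) -> float:
    """Two-sided McNemar p-value from discordant counts (b, c).

    Exact binomial when b + c < ``exact_below``; otherwise the chi-square
    statistic with continuity correction.  b = c = 0 returns p = 1 by
    convention (no discordance, no evidence).
    """
    b, c = int(b), int(c)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    m = b + c
    if m == 0:
        return 1.0
    if m < exact_below:
        p = 2.0 * binom.cdf(min(b, c), m, 0.5)
        return float(min(1.0, p))
    stat = (abs(b - c) - 1) ** 2 / m
    return float(chi2.sf(stat, 1))


def holm(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, in the original order."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = (m - rank) * p[idx]
        running = max(running, val)
        adj[idx] = min(1.0, running)
    return adj


def bootstrap_two_sided_p(deltas, plus_one: bool = True) -> float:
    """Two-sided Monte-Carlo p for a bootstrap replicate vector of deltas.

    ``p = 2 * min(frac(delta <= 0), frac(delta >= 0))`` with the plus-one
    correction (count+1)/(B+1) when ``plus_one``, capped at 1.
    """
    d = np.asarray(deltas, dtype=float)
    B = len(d)
    if B == 0:
        raise ValueError("no bootstrap replicates")
    le = (d <= 0).sum()
    ge = (d >= 0).sum()
    if plus_one:
        p = 2.0 * min((le + 1) / (B + 1), (ge + 1) / (B + 1))
    else:
        p = 2.0 * min(le / B, ge / B)
    return float(min(1.0, p))
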