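"""Repeated stratified k-fold assignments with tight balance guarantees.

Within every repeat, per-fold positive counts differ by at most one, per-fold
negative counts differ by at most one, and per-fold total sizes differ by at
most one.  Repeat r uses seed + r, so assignments are reproducible and
repeats are independent.
"""

from __future__ import annotations

import numpy as np

_MOD = 2**31


def make_folds(labels, k: int, repeats: int, seed: int) -> np.ndarray:
    """Fold assignment array of shape (repeats, n) with values in 0..k-1."""
    y = np.asarray(labels).astype(int)
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be binary")
    n = len(y)
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if min(n_pos, n_neg) < k:
        raise ValueError(
            f"each class must have at least k={k} members (got {n_pos} positives, {n_neg} negatives)"
        )
    out = np.empty((repeats, n), dtype=int)
    pos_idx = np.where(y == 1)[0]
    neg_idx = np.where(y == 0)[0]
    a, b = n_pos % k, n_neg % k
    for r in range(repeats):
        rng = np.random.default_rng((seed + r) % _MOD)
        perm = rng.permutation(k)
        # extras placed so fold totals stay within one of each other:
        # positive extras on perm[:a], negative extras on perm[k-b:]
        pos_counts = np.full(k, n_pos // k)
        pos_counts[perm[:a]] += 1
        neg_counts = np.full(k, n_neg // k)
        if b:
            neg_counts[perm[k - b :]] += 1
        assign = out[r]
        assign[rng.permutation(pos_idx)] = np.repeat(np.arange(k), pos_counts)
        assign[rng.permutation(neg_idx)] = np.repeat(np.arange(k), neg_counts)
    return out
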