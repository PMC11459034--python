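"""Independent brute-force oracles used by the test suite.

These are deliberately naive implementations (exact integer enumeration,
pair counting) kept independent of the package code paths they check.
"""

from __future__ import annotations

from math import comb

import numpy as np


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration.

    Enumerates every table with the observed margins, using exact integer
    arithmetic, and sums the probabilities of tables no more probable than
    the observed one.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    numerators = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    observed = numerators[a - lo]
    total = sum(v for v in numerators if v <= observed)
    return total / denom


def auc_pair_counting_oracle(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney concordance probability by explicit pair
    counting (ties credited 1/2)."""
    y = np.asarray(y, dtype=int)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes")
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pearson_r_closed_form(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson correlation from raw sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x**2).sum() - sx**2) * np.sqrt(n * (y**2).sum() - sy**2)
    return num / den
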