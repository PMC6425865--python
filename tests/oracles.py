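"""Independent oracles used by the test suite.

Deliberately dumber and slower than the library: exact rational arithmetic
and naive enumeration, sharing no code with the implementations they check.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product
from math import factorial

import numpy as np
from scipy.stats import hypergeom


def fisher_rxc_exact_fraction(counts) -> Fraction:
    """Freeman–Halton p by brute force over all margin-fixed tables,
    computed in exact rational arithmetic (no floats anywhere)."""
    obs = [list(map(int, r)) for r in counts]
    r, c = len(obs), len(obs[0])
    row = [sum(x) for x in obs]
    col = [sum(obs[i][j] for i in range(r)) for j in range(c)]
    n = sum(row)
    const = Fraction(1)
    for x in row:
        const *= factorial(x)
    for x in col:
        const *= factorial(x)
    const /= factorial(n)

    def prob(t) -> Fraction:
        d = 1
        for rr in t:
            for v in rr:
                d *= factorial(v)
        return const / d

    p_obs = prob(obs)
    total = Fraction(0)
    psum = Fraction(0)
    ranges = [range(min(row[i], col[j]) + 1) for i in range(r - 1) for j in range(c - 1)]
    for vals in product(*ranges):
        t = [[0] * c for _ in range(r)]
        k = 0
        for i in range(r - 1):
            for j in range(c - 1):
                t[i][j] = vals[k]
                k += 1
        ok = True
        for i in range(r - 1):
            rem = row[i] - sum(t[i][: c - 1])
            if rem < 0:
                ok = False
                break
            t[i][c - 1] = rem
        if ok:
            for j in range(c):
                rem = col[j] - sum(t[i][j] for i in range(r - 1))
                if rem < 0:
                    ok = False
                    break
                t[r - 1][j] = rem
        if not ok:
            continue
        p = prob(t)
        total += p
        if p <= p_obs:
            psum += p
    assert total == 1
    return psum


def fisher_2x2_hypergeom(a: int, b: int, c: int, d: int, rel_tol: float = 1e-7) -> float:
    """2x2 Fisher p via the hypergeometric pmf tail (as-or-less-probable)."""
    n = a + b + c + d
    r0 = a + b
    c0 = a + c
    lo, hi = max(0, r0 + c0 - n), min(r0, c0)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, n, r0, c0)
    p_obs = pmf[a - lo]
    return float(pmf[pmf <= p_obs * (1.0 + rel_tol)].sum())


def chi2_by_hand(counts) -> tuple[float, int]:
    """Pearson statistic from first principles: sum (O-E)^2/E."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n
    stat = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return stat, df
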