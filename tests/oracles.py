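"""Independent brute-force oracles for exact 2x2 inference.

These deliberately share no code path with the package implementation:
probabilities come from ``scipy.stats.hypergeom`` pmf values reweighted by
plain powers of the odds parameter, and confidence limits are located by
naive bisection on a log grid. They are slow and simple on purpose.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import hypergeom

TIE_GAMMA = 1 + 1e-14  # minimum-likelihood tie tolerance


def support(a: int, b: int, c: int, d: int) -> np.ndarray:
    n_total, row1, col1 = a + b + c + d, a + b, a + c
    lo = max(0, col1 - (n_total - row1))
    hi = min(row1, col1)
    return np.arange(lo, hi + 1)


def null_pmf(a: int, b: int, c: int, d: int) -> tuple[np.ndarray, np.ndarray]:
    k = support(a, b, c, d)
    n_total, row1, col1 = a + b + c + d, a + b, a + c
    return k, hypergeom.pmf(k, n_total, row1, col1)


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact p by direct summation of the minimum-likelihood rule."""
    k, pmf = null_pmf(a, b, c, d)
    if len(k) == 1:
        return 1.0  # single-outcome support: the observed table is certain
    p_obs = pmf[int(a - k[0])]
    return float(min(1.0, pmf[pmf <= p_obs * TIE_GAMMA].sum()))


def _weights(pmf: np.ndarray, k: np.ndarray, psi: float) -> np.ndarray:
    # stable reweighting: constant factors cancel under normalization
    e = (k - k[0]) * math.log(psi)
    w = pmf * np.exp(e - e.max())
    return w / w.sum()


def tail_ge(a: int, k: np.ndarray, pmf: np.ndarray, psi: float) -> float:
    w = _weights(pmf, k, psi)
    return float(w[k >= a].sum())


def tail_le(a: int, k: np.ndarray, pmf: np.ndarray, psi: float) -> float:
    w = _weights(pmf, k, psi)
    return float(w[k <= a].sum())


def exact_ci_bisection(
    a: int, b: int, c: int, d: int, alpha: float = 0.05, tol: float = 1e-9
) -> tuple[float, float] | None:
    """Cornfield limits by coarse grid bracketing plus bisection on log psi."""
    k, pmf = null_pmf(a, b, c, d)
    if len(k) == 1:
        return None
    half = alpha / 2.0

    def bisect(f) -> float:
        # f is increasing in log psi; find sign change on a coarse grid
        grid = np.arange(-60.0, 60.0 + 1e-9, 5.0)
        vals = [f(g) for g in grid]
        lo = hi = None
        for g, v, g2, v2 in zip(grid, vals, grid[1:], vals[1:]):
            if v <= 0 <= v2:
                lo, hi = g, g2
                break
        if lo is None:
            raise AssertionError("oracle failed to bracket root")
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if f(mid) <= 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    if a == k[0]:
        low = 0.0
    else:
        low = math.exp(bisect(lambda s: tail_ge(a, k, pmf, math.exp(s)) - half))
    if a == k[-1]:
        high = math.inf
    else:
        high = math.exp(bisect(lambda s: half - tail_le(a, k, pmf, math.exp(s))))
    return low, high


def all_tables(total_max: int, total_min: int = 0):
    """Yield every (a, b, c, d) with total_min <= a+b+c+d <= total_max."""
    for n in range(total_min, total_max + 1):
        for a, b, c in itertools.product(range(n + 1), repeat=3):
            d = n - a - b - c
            if d >= 0:
                yield a, b, c, d
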