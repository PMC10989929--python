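"""Independent brute-force oracles used to cross-check the library.

These deliberately avoid the library's own code paths: the scanner
oracle is a naive per-bond loop, the U-tract oracle a manual run
enumeration, and the decay oracle an exhaustive lattice search over
(lambda, N0) rather than a gradient-based solver.
"""

from __future__ import annotations

import numpy as np


def brute_force_scan(seq: str) -> list[tuple[int, bool, bool]]:
    """Enumerate every bond and test the two cleavage rules literally.

    Returns (bond, plus2_u, minus34_a) for bonds matching >= 1 rule,
    both-rule bonds first, each group in position order.
    """
    n = len(seq)
    hits = []
    for b in range(3, n - 1):          # b-2 >= 1 and b+2 <= n, 1-based
        plus2 = seq[b + 2 - 1] == "U"
        minus3 = seq[b - 2 - 1] == "A"
        minus4 = b - 3 >= 1 and seq[b - 3 - 1] == "A"
        minus34 = minus3 or minus4
        if plus2 or minus34:
            hits.append((b, plus2, minus34))
    hits.sort(key=lambda h: (not (h[1] and h[2]), h[0]))
    return hits


def brute_force_u_tracts(seq: str, min_len: int) -> list[tuple[int, int]]:
    """Manual enumeration of maximal U-runs (1-based inclusive)."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "U":
            j = i
            while j < n and seq[j] == "U":
                j += 1
            if j - i >= min_len:
                runs.append((i + 1, j))
            i = j
        else:
            i += 1
    return runs


def grid_search_decay(
    t: np.ndarray,
    rq: np.ndarray,
    n_grid: int = 2000,
) -> tuple[float, float, float]:
    """Exhaustive RSS minimisation of N0*exp(-lambda t) on an n_grid^2 lattice.

    The lattice spans a factor of [1/2, 2] around log-linear OLS start
    values, log-spaced, which brackets any reasonable optimum for the
    noise levels used in tests.  Returns (lambda, n0, rss) at the best
    lattice point.
    """
    t = np.asarray(t, float)
    rq = np.asarray(rq, float)
    slope, intercept = np.polyfit(t, np.log(rq), 1)
    lam0 = max(-slope, 1e-6)
    n0_0 = float(np.exp(intercept))
    lams = np.geomspace(lam0 / 2, lam0 * 2, n_grid)
    n0s = np.geomspace(n0_0 / 2, n0_0 * 2, n_grid)
    # RSS(lam, n0) = c - 2 n0 a(lam) + n0^2 b(lam): evaluate on the full lattice
    e = np.exp(-np.outer(lams, t))          # (n_grid, n_pts)
    a = e @ rq
    b = (e * e).sum(axis=1)
    c = float(rq @ rq)
    rss = c - 2.0 * np.outer(a, n0s) + np.outer(b, n0s**2)
    i, j = np.unravel_index(np.argmin(rss), rss.shape)
    return float(lams[i]), float(n0s[j]), float(rss[i, j])
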