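"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity by the most direct method available
(enumeration, nested loops, grid search) without sharing any code with the
package implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def bce_by_loop(target: np.ndarray, output: np.ndarray) -> float:
    """Binary cross-entropy as an explicit elementwise sum."""
    t = np.asarray(target, dtype=float).ravel()
    o = np.asarray(output, dtype=float).ravel()
    total = 0.0
    for ti, oi in zip(t, o):
        total += -(ti * np.log(oi) + (1 - ti) * np.log(1 - oi))
    return total / len(t)


def fisher_by_enumeration(table) -> float:
    """Two-sided Fisher p by summing hypergeometric probabilities of all
    tables with the observed margins that are no more probable."""
    a, b, c, d = np.asarray(table).ravel()
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    probs = hypergeom.pmf(np.arange(lo, hi + 1), n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


def breslow_loglik(b: float, x: np.ndarray, t: np.ndarray, d: np.ndarray) -> float:
    """Breslow partial log-likelihood by direct risk-set loops."""
    ll = 0.0
    for i in range(len(t)):
        if d[i] == 1:
            risk = np.exp(b * x[t >= t[i]]).sum()
            ll += b * x[i] - np.log(risk)
    return ll


def cox_by_grid(x, t, d, lo=-30.0, hi=30.0) -> float:
    """Maximize the Breslow partial likelihood by iterated grid refinement."""
    for _ in range(8):
        grid = np.linspace(lo, hi, 201)
        lls = [breslow_loglik(b, x, t, d) for b in grid]
        i = int(np.argmax(lls))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    return float(grid[i])


def complete_linkage_heights(points: np.ndarray) -> list[float]:
    """O(n^3) agglomeration: merge heights under complete linkage."""
    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dmax = max(
                    np.linalg.norm(points[a] - points[b])
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if dmax < best[0]:
                    best = (dmax, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights


def gene_trace_by_loop(W: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Per-gene weighted sum as an explicit double loop."""
    g, k = W.shape
    out = np.zeros(g)
    for gi in range(g):
        for ki in range(k):
            out[gi] += W[gi, ki] * B[ki]
    return out
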