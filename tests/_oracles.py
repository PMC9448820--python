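"""Independent brute-force oracles used by the test suite.

Everything here is implemented with explicit loops, ``math`` scalars and
log-gamma — deliberately sharing no code with the package — so that
agreement is a real dual-route check.
"""

from __future__ import annotations

import math

import numpy as np


def t_density_kernel(d: float, nu: float) -> float:
    """Student-t kernel of a single distance via log-gamma."""
    log_c = math.lgamma((nu + 1.0) / 2.0) - math.lgamma(nu / 2.0) - 0.5 * math.log(nu * math.pi)
    return math.exp(log_c) * (1.0 + d * d / nu) ** (-(nu + 1.0) / 2.0)


def symmetrize_loops(A: np.ndarray) -> np.ndarray:
    n, m = A.shape
    out = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            out[i, j] = A[i, j] + A[j, i] - 2.0 * A[i, j] * A[j, i]
    return out


def similarities_loops(X: np.ndarray, nu: float, eps: float) -> np.ndarray:
    n = X.shape[0]
    M = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d = math.sqrt(sum((X[i, k] - X[j, k]) ** 2 for k in range(X.shape[1])))
            M[i, j] = 2.0 * math.pi * t_density_kernel(d, nu) ** 2
    S = symmetrize_loops(M)
    for i in range(n):
        for j in range(n):
            S[i, j] = min(max(S[i, j], eps), 1.0 - eps)
    return S


def bernoulli_kl(p: float, q: float) -> float:
    return p * math.log(p / q) + (1.0 - p) * math.log((1.0 - p) / (1.0 - q))


def two_way_divergence_loops(P: np.ndarray, Q: np.ndarray) -> float:
    total = 0.0
    n = P.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j:
                total += bernoulli_kl(P[i, j], Q[i, j])
    return total


def weighted_ce_loops(y, p_benign, beta: float, eps: float) -> float:
    total = 0.0
    for yi, pi in zip(y, p_benign):
        pi = min(max(pi, eps), 1.0 - eps)
        total += beta * yi * math.log(pi) + (2.0 - beta) * (1.0 - yi) * math.log(1.0 - pi)
    return -total


def wilson_closed_form(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Textbook Wilson score interval."""
    from scipy.stats import norm

    z = norm.ppf(1.0 - (1.0 - level) / 2.0)
    phat = k / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return center - half, center + half


def auc_pair_count(scores, labels_positive) -> float:
    """AUC by exhaustive O(n^2) pair comparison with half-credit ties."""
    pos = [s for s, l in zip(scores, labels_positive) if l]
    neg = [s for s, l in zip(scores, labels_positive) if not l]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def spearman_loops(x, y) -> float:
    """Rank correlation from the Pearson formula on midranks."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den
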