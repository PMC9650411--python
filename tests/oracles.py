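"""Independent brute-force oracles used to validate the implementation.

Each oracle is deliberately naive (enumeration, triple loops, residual
regressions, generalized eigenproblems) and shares no code with the package
paths it checks.
"""

from __future__ import annotations

from math import comb

import numpy as np


def hypergeom_tail_exact(n1: int, m1: int, k1: int, l1: int) -> float:
    """P(X >= l1) by exact integer enumeration of the hypergeometric pmf."""
    total = comb(n1, k1)
    acc = 0
    for i in range(l1, min(m1, k1) + 1):
        if k1 - i <= n1 - m1:
            acc += comb(m1, i) * comb(n1 - m1, k1 - i)
    return acc / total


def tom_brute_force(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap of an adjacency with unit diagonal."""
    n = a.shape[0]
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a0[i, u] * a0[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a0[i, j]) / (min(k[i], k[j]) + 1.0 - a0[i, j])
    return tom


def first_cc_eigen(x: np.ndarray, y: np.ndarray) -> float:
    """First canonical correlation via the generalized eigenproblem on
    the full covariance matrices (no dimensionality guard)."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sxx = xc.T @ xc
    syy = yc.T @ yc
    sxy = xc.T @ yc
    m = np.linalg.solve(sxx, sxy) @ np.linalg.solve(syy, sxy.T)
    eig = np.linalg.eigvals(m)
    return float(np.sqrt(np.clip(np.max(eig.real), 0.0, 1.0)))


def partial_corr_residual(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Classical first-order partial correlation via regression residuals."""
    zc = np.column_stack([np.ones_like(z), z])
    rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
    ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def auc_pair_count(values: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC by counting all case/control pairs, ties as 1/2."""
    cases = values[labels == 1]
    controls = values[labels == 0]
    wins = 0.0
    for c in cases:
        for d in controls:
            if c > d:
                wins += 1.0
            elif c == d:
                wins += 0.5
    return wins / (len(cases) * len(controls))


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, written out longhand."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvals[idx] * m / rank)
        adj[idx] = running
    return adj
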