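"""Brute-force reference implementations used only to check the package.

Everything here is written in the most literal way possible (scalar loops,
exhaustive enumeration) and stays independent of the code paths it verifies.
"""

from __future__ import annotations

import numpy as np


def strength_loop(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i] += W[i, j]
    return out


def onnela_clustering_loop(W: np.ndarray) -> np.ndarray:
    """Geometric-mean triangle clustering on max-normalized weights."""
    n = W.shape[0]
    wmax = W.max()
    if wmax == 0:
        return np.zeros(n)
    What = W / wmax
    out = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if j != i and W[i, j] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                total += (What[i, j] * What[i, h] * What[j, h]) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def floyd_warshall_loop(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths with lengths 1/w, by the textbook recursion."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    for i in range(n):
        D[i, i] = 0.0
        for j in range(n):
            if i != j and W[i, j] > 0:
                D[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def path_length_loop(D: np.ndarray) -> float:
    vals = [
        D[i, j]
        for i in range(D.shape[0])
        for j in range(D.shape[0])
        if i != j and np.isfinite(D[i, j])
    ]
    return float(np.mean(vals)) if vals else float("inf")


def efficiency_loop(D: np.ndarray) -> float:
    vals = []
    for i in range(D.shape[0]):
        for j in range(D.shape[0]):
            if i != j:
                vals.append(1.0 / D[i, j] if np.isfinite(D[i, j]) else 0.0)
    return float(np.mean(vals))


def bh_loop(p: list[float]) -> list[float]:
    """Benjamini-Hochberg by the step-up definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = min(val, 1.0)
        prev = val
    return adj


def anova_F_loop(values: np.ndarray, groups: np.ndarray) -> float:
    """Classical one-way ANOVA F from group/overall means."""
    labels = sorted(set(groups.tolist()))
    grand = values.mean()
    ss_between = sum(
        (groups == g).sum() * (values[groups == g].mean() - grand) ** 2
        for g in labels
    )
    ss_within = sum(
        ((values[groups == g] - values[groups == g].mean()) ** 2).sum()
        for g in labels
    )
    df1 = len(labels) - 1
    df2 = len(values) - len(labels)
    return (ss_between / df1) / (ss_within / df2)


def partial_corr_loop(x, y, Z) -> float:
    """Residual correlation computed scalar-wise via normal equations."""
    n = len(x)
    design = np.column_stack([np.ones(n), np.atleast_2d(Z).reshape(n, -1)])
    bx = np.linalg.solve(design.T @ design, design.T @ x)
    by = np.linalg.solve(design.T @ design, design.T @ y)
    rx = x - design @ bx
    ry = y - design @ by
    return float(
        np.sum(rx * ry) / np.sqrt(np.sum(rx * rx) * np.sum(ry * ry))
    )


def random_weight_matrix(rng: np.random.Generator, n: int, density: float = 0.7):
    """A random symmetric zero-diagonal weight matrix with entries in [0, 1]."""
    W = rng.uniform(0.05, 1.0, size=(n, n))
    mask = rng.uniform(size=(n, n)) < density
    W = np.triu(W * mask, k=1)
    W = W + W.T
    return W
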