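"""Independent brute-force oracles used across the test suite.

Everything here is written directly from the mathematical definitions
(explicit loops, no shared code with the package) so that agreement between
the package and these functions is informative.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def circular_mean_direct(phi) -> float:
    s = sum(math.sin(v) for v in phi)
    c = sum(math.cos(v) for v in phi)
    return math.atan2(s, c)


def ccor_direct(phi_i, phi_j) -> float:
    """The circular correlation formula, term by term."""
    mi = circular_mean_direct(phi_i)
    mj = circular_mean_direct(phi_j)
    num = sum(math.sin(a - mi) * math.sin(b - mj) for a, b in zip(phi_i, phi_j))
    den_i = sum(math.sin(a - mi) ** 2 for a in phi_i)
    den_j = sum(math.sin(b - mj) ** 2 for b in phi_j)
    return num / math.sqrt(den_i * den_j)


def pearson_direct(u, v) -> float:
    n = len(u)
    mu, mv = sum(u) / n, sum(v) / n
    num = sum((a - mu) * (b - mv) for a, b in zip(u, v))
    du = math.sqrt(sum((a - mu) ** 2 for a in u))
    dv = math.sqrt(sum((b - mv) ** 2 for b in v))
    return num / (du * dv)


def dfc_direct(matrices) -> np.ndarray:
    """Double-loop Pearson recurrence over strict upper triangles."""
    nw = len(matrices)
    n = matrices[0].shape[0]
    tris = []
    for w in range(nw):
        tris.append([matrices[w][i, j] for i in range(n) for j in range(i + 1, n)])
    out = np.empty((nw, nw))
    for a in range(nw):
        for b in range(nw):
            out[a, b] = 1.0 if a == b else pearson_direct(tris[a], tris[b])
    return out


def fluidity_direct(dfc) -> float:
    """Population variance of the strict upper triangle."""
    n = dfc.shape[0]
    vals = [dfc[i, j] for i in range(n) for j in range(i + 1, n)]
    mean = sum(vals) / len(vals)
    return sum((v - mean) ** 2 for v in vals) / len(vals)


def pli_direct(phi_i, phi_j) -> float:
    total = 0.0
    for a, b in zip(phi_i, phi_j):
        d = a - b
        while d <= -math.pi:
            d += 2 * math.pi
        while d > math.pi:
            d -= 2 * math.pi
        total += 0.0 if d == 0 else (1.0 if d > 0 else -1.0)
    return abs(total / len(phi_i))


def node_strength_direct(w) -> float:
    n = w.shape[0]
    return sum(sum(w[i, j] for j in range(n)) for i in range(n)) / n


def onnela_clustering_direct(w) -> float:
    """Triple-loop Onnela weighted clustering, weights max-normalized."""
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        k = sum(1 for j in range(n) if w[i, j] > 0 and j != i)
        if k < 2:
            continue
        tri = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                tri += ((w[i, j] / wmax) * (w[i, h] / wmax) * (w[j, h] / wmax)) ** (
                    1.0 / 3.0
                )
        total += tri / (k * (k - 1))
    return total / n


def char_path_direct(w) -> float:
    """Floyd-Warshall on 1/weight distances; mean over reachable ordered pairs."""
    n = w.shape[0]
    dist = [[math.inf] * n for _ in range(n)]
    for i in range(n):
        dist[i][i] = 0.0
        for j in range(n):
            if i != j and w[i, j] > 0:
                dist[i][j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    vals = [dist[i][j] for i in range(n) for j in range(n) if i != j
            and math.isfinite(dist[i][j])]
    return sum(vals) / len(vals)


def modularity_direct(w, labels) -> float:
    W = w.sum()
    s = w.sum(axis=1)
    q = 0.0
    for c in set(labels):
        idx = [i for i, l in enumerate(labels) if l == c]
        q += sum(w[i, j] for i in idx for j in idx) / W
        q -= (sum(s[i] for i in idx) / W) ** 2
    return q


def _partitions_rgs(n: int, max_k: int | None = None):
    """All set partitions of range(n) as restricted-growth strings:
    a[0] = 0 and a[i] <= max(a[:i]) + 1, capped at max_k parts."""
    a = [0] * n

    def rec(i: int, mx: int):
        if i == n:
            yield a[:]
            return
        hi = mx + 1
        if max_k is not None:
            hi = min(hi, max_k - 1)
        for v in range(hi + 1):
            a[i] = v
            yield from rec(i + 1, max(mx, v))

    yield from rec(1, 0)


def best_modularity_exhaustive(w, max_k: int | None = None) -> tuple[float, list]:
    """Global maximum of Q over all set partitions (optionally <= max_k parts)."""
    best_q, best = -math.inf, None
    for labels in _partitions_rgs(w.shape[0], max_k=max_k):
        q = modularity_direct(w, labels)
        if q > best_q:
            best_q, best = q, labels
    return best_q, best


def best_modularity_exhaustive_fast(w, max_k: int | None = None) -> float:
    """Vectorized exhaustive Q maximization for slightly larger n."""
    n = w.shape[0]
    W = w.sum()
    s = w.sum(axis=1)
    parts = np.array(list(_partitions_rgs(n, max_k=max_k)), dtype=np.int64)
    best = -math.inf
    k = int(parts.max()) + 1
    for start in range(0, len(parts), 20000):
        chunk = parts[start : start + 20000]
        onehot = np.eye(k)[chunk]  # (B, n, k)
        within = np.einsum("bik,ij,bjk->b", onehot, w, onehot)
        sums = np.einsum("bik,i->bk", onehot, s)
        q = within / W - (sums**2).sum(axis=1) / W**2
        best = max(best, float(q.max()))
    return best


def mahalanobis_direct(x) -> np.ndarray:
    """Explicit-inverse Mahalanobis distance matrix."""
    n, p = x.shape
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (n - 1)
    inv = np.linalg.inv(cov)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d = x[i] - x[j]
            out[i, j] = math.sqrt(float(d @ inv @ d))
    return out


def bh_adjust_direct(p) -> np.ndarray:
    """Benjamini-Hochberg step-up written from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
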