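"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: distances and
betweenness are computed by exhaustive enumeration of simple paths, and the
uncorrected two-proportion chi-square by the textbook pooled z statistic.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def exhaustive_distances(beta: np.ndarray) -> np.ndarray:
    """All-pairs shortest distances (edge length 1/|w|) by enumerating every
    simple path.  Exponential; only for tiny graphs."""
    p = beta.shape[0]
    with np.errstate(divide="ignore"):
        length = np.where(beta != 0, 1.0 / np.abs(beta), np.inf)
    dist = np.full((p, p), np.inf)
    np.fill_diagonal(dist, 0.0)
    for s in range(p):
        for t in range(p):
            if s == t:
                continue
            best = length[s, t]
            inner = [v for v in range(p) if v not in (s, t)]
            for r in range(1, p - 1):
                for mid in permutations(inner, r):
                    nodes = (s, *mid, t)
                    d = sum(length[a, b] for a, b in zip(nodes, nodes[1:]))
                    best = min(best, d)
            dist[s, t] = best
    return dist


def exhaustive_closeness(beta: np.ndarray) -> np.ndarray:
    dist = exhaustive_distances(beta)
    total = dist.sum(axis=1)
    out = np.zeros(beta.shape[0])
    ok = np.isfinite(total) & (total > 0)
    out[ok] = 1.0 / total[ok]
    return out


def exhaustive_betweenness(beta: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Fractional shortest-path counts through each node, over unordered
    pairs of the other nodes, enumerating every simple path."""
    p = beta.shape[0]
    with np.errstate(divide="ignore"):
        length = np.where(beta != 0, 1.0 / np.abs(beta), np.inf)
    out = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            paths = []
            inner = [v for v in range(p) if v not in (s, t)]
            for r in range(p - 1):
                for mid in permutations(inner, r):
                    nodes = (s, *mid, t)
                    d = sum(length[a, b] for a, b in zip(nodes, nodes[1:]))
                    if np.isfinite(d):
                        paths.append((d, set(mid)))
            if not paths:
                continue
            dmin = min(d for d, _ in paths)
            shortest = [mid for d, mid in paths if d <= dmin + tol]
            for v in range(p):
                if v in (s, t):
                    continue
                out[v] += sum(v in mid for mid in shortest) / len(shortest)
    return out


def pooled_z_squared(k1: int, n1: int, k2: int, n2: int) -> float:
    """Square of the pooled-variance two-proportion z statistic."""
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    return float(((p1 - p2) / se) ** 2)


def random_sparse_network(p: int, seed: int, density: float = 0.5):
    """Random symmetric sparse weight matrix for centrality oracle checks."""
    rng = np.random.default_rng(seed)
    beta = np.zeros((p, p))
    for j in range(p):
        for k in range(j + 1, p):
            if rng.random() < density:
                w = rng.uniform(0.2, 1.5) * rng.choice([-1.0, 1.0])
                beta[j, k] = beta[k, j] = w
    return beta
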