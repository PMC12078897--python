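"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: explicit voxel loops, exhaustive
pair/run/zone enumeration, O(n^2) concordance counting.  None of it shares
code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np

OFFSETS_26 = [
    (i, j, k)
    for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


def _inside(pos, shape):
    return all(0 <= p < s for p, s in zip(pos, shape))


def glcm_bruteforce(q: np.ndarray, n_levels: int, offset) -> np.ndarray:
    """Symmetric co-occurrence counts by explicit voxel-pair enumeration."""
    P = np.zeros((n_levels, n_levels))
    for pos in np.ndindex(q.shape):
        if q[pos] == 0:
            continue
        for d in (offset, tuple(-o for o in offset)):
            nb = tuple(p + o for p, o in zip(pos, d))
            if _inside(nb, q.shape) and q[nb] > 0:
                P[q[pos] - 1, q[nb] - 1] += 1
    return P


def glrlm_bruteforce(q: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Run-length counts by walking every maximal run voxel by voxel."""
    runs = []
    d = tuple(direction)
    for pos in np.ndindex(q.shape):
        if q[pos] == 0:
            continue
        prev = tuple(p - o for p, o in zip(pos, d))
        if _inside(prev, q.shape) and q[prev] == q[pos]:
            continue  # not the start of a run
        length = 1
        nxt = tuple(p + o for p, o in zip(pos, d))
        while _inside(nxt, q.shape) and q[nxt] == q[pos]:
            length += 1
            nxt = tuple(p + o for p, o in zip(nxt, d))
        runs.append((q[pos], length))
    max_len = max((l for _, l in runs), default=1)
    P = np.zeros((n_levels, max_len))
    for lev, l in runs:
        P[lev - 1, l - 1] += 1
    return P


def glszm_bruteforce(q: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone counts by flood fill over 26-connected equal-level components."""
    seen = np.zeros(q.shape, dtype=bool)
    zones = []
    for pos in np.ndindex(q.shape):
        if q[pos] == 0 or seen[pos]:
            continue
        level = q[pos]
        stack, size = [pos], 0
        seen[pos] = True
        while stack:
            cur = stack.pop()
            size += 1
            for off in OFFSETS_26:
                nb = tuple(c + o for c, o in zip(cur, off))
                if _inside(nb, q.shape) and not seen[nb] and q[nb] == level:
                    seen[nb] = True
                    stack.append(nb)
        zones.append((level, size))
    max_size = max((s for _, s in zones), default=1)
    P = np.zeros((n_levels, max_size))
    for lev, s in zones:
        P[lev - 1, s - 1] += 1
    return P


def gldm_bruteforce(q: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts: per voxel, #26-neighbours within alpha of its level."""
    entries = []
    for pos in np.ndindex(q.shape):
        if q[pos] == 0:
            continue
        dep = 0
        for off in OFFSETS_26:
            nb = tuple(p + o for p, o in zip(pos, off))
            if _inside(nb, q.shape) and q[nb] > 0 and abs(int(q[nb]) - int(q[pos])) <= alpha:
                dep += 1
        entries.append((q[pos], dep))
    max_dep = max((d for _, d in entries), default=0)
    P = np.zeros((n_levels, max_dep + 1))
    for lev, d in entries:
        P[lev - 1, d] += 1
    return P


def ngtdm_bruteforce(q: np.ndarray, n_levels: int):
    """(n_i, p_i, s_i) by per-voxel neighbourhood averaging."""
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for pos in np.ndindex(q.shape):
        if q[pos] == 0:
            continue
        nb_vals = [
            q[tuple(p + o for p, o in zip(pos, off))]
            for off in OFFSETS_26
            if _inside(tuple(p + o for p, o in zip(pos, off)), q.shape)
            and q[tuple(p + o for p, o in zip(pos, off))] > 0
        ]
        if not nb_vals:
            continue
        n_i[q[pos] - 1] += 1
        s_i[q[pos] - 1] += abs(q[pos] - np.mean(nb_vals))
    total = n_i.sum()
    p_i = n_i / total if total else n_i
    return n_i, p_i, s_i


def auc_bruteforce(scores, labels) -> float:
    """Fraction of concordant positive-negative pairs, ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def fisher_exact_bruteforce(table) -> float:
    """Two-sided Fisher p by hypergeometric enumeration over all tables."""
    from math import comb

    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(0, min(r1, c1) + 1) if prob(x) <= p_obs * (1 + 1e-9))


def kmeans_sse_bruteforce_restarts(x: np.ndarray, k: int, n_restarts: int = 100, seed: int = 0) -> float:
    """Best SSE over many independent Lloyd runs, D^2-weighted init (1-D)."""
    rng = np.random.default_rng(seed)

    def _init():
        cs = [x[rng.integers(x.size)]]
        for _ in range(k - 1):
            d2 = np.min(np.abs(x[:, None] - np.asarray(cs)[None, :]) ** 2, axis=1)
            cs.append(x[rng.choice(x.size, p=d2 / d2.sum())] if d2.sum() > 0 else x[rng.integers(x.size)])
        return np.asarray(cs, dtype=float)

    best = np.inf
    for _ in range(n_restarts):
        centers = _init()
        for _ in range(200):
            d = np.abs(x[:, None] - centers[None, :])
            lab = d.argmin(axis=1)
            new = np.array([x[lab == c].mean() if (lab == c).any() else centers[c] for c in range(k)])
            if np.allclose(new, centers, atol=1e-12):
                break
            centers = new
        sse = sum(((x[lab == c] - centers[c]) ** 2).sum() for c in range(k))
        best = min(best, sse)
    return float(best)
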