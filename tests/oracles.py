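"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the library's own code paths: trajectory matrices
via an explicit double loop over TR pairs with the textbook Pearson
formula, and HMM likelihoods via exhaustive enumeration of every monotone
state path.
"""

from __future__ import annotations

import math

import numpy as np


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    denom = math.sqrt((xm**2).sum() * (ym**2).sum())
    return float((xm * ym).sum() / denom)


def naive_trajectory_matrix(data: np.ndarray) -> np.ndarray:
    """Double-loop TR x TR Pearson matrix from a voxels x TRs array."""
    t = data.shape[1]
    out = np.empty((t, t))
    for i in range(t):
        for j in range(t):
            out[i, j] = pearson(data[:, i], data[:, j])
    return out

def naive_ists(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of the strict upper triangles of two matrices."""
    iu = np.triu_indices(a.shape[0], k=1)
    return pearson(a[iu], b[iu])


def all_derangements(n: int) -> list[tuple[int, ...]]:
    """Every permutation of range(n) without fixed points."""
    from itertools import permutations

    return [p for p in permutations(range(n)) if all(p[i] != i for i in range(n))]


def enumerate_monotone_loglik(
    X: np.ndarray, means: np.ndarray, var: float, advance_prob: float
) -> float:
    """Total log-likelihood by summing over every monotone state path.

    Paths start in state 0 and at each step stay or advance by one state
    (the last state is absorbing). Emissions are isotropic Gaussians with
    shared variance. Feasible only for tiny T and K.
    """
    t_len, d = X.shape
    k = means.shape[0]

    def log_emission(t: int, s: int) -> float:
        diff = X[t] - means[s]
        return -0.5 * (d * math.log(2 * math.pi * var) + float(diff @ diff) / var)

    def log_trans(s: int, s2: int) -> float:
        if s == k - 1:
            return 0.0 if s2 == s else -math.inf
        if s2 == s:
            return math.log1p(-advance_prob) if advance_prob < 1 else -math.inf
        if s2 == s + 1:
            return math.log(advance_prob) if advance_prob > 0 else -math.inf
        return -math.inf

    path_lls = []

    def recurse(t: int, s: int, acc: float) -> None:
        if t == t_len:
            path_lls.append(acc)
            return
        for s2 in (s, s + 1):
            if s2 >= k:
                continue
            lt = log_trans(s, s2)
            if lt == -math.inf:
                continue
            recurse(t + 1, s2, acc + lt + log_emission(t, s2))

    recurse(1, 0, log_emission(0, 0))
    m = max(path_lls)
    return m + math.log(sum(math.exp(v - m) for v in path_lls))


def bh_reject(p_values: np.ndarray, q: float) -> np.ndarray:
    """Hand Benjamini-Hochberg: largest k with p_(k) <= k q / m, reject prefix."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    thresh = q * (np.arange(1, m + 1)) / m
    below = np.flatnonzero(p[order] <= thresh)
    mask = np.zeros(m, dtype=bool)
    if below.size:
        mask[order[: below[-1] + 1]] = True
    return mask
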