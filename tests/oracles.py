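"""Independent brute-force oracles used by the test suite.

Everything here is written as plainly as possible — per-pixel and per-pair
Python loops, full enumeration of sign patterns and rank subsets — and is
deliberately independent of the package's vectorized implementations.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np

# ---------------------------------------------------------------------------
# Region features
# ---------------------------------------------------------------------------

def brute_echogenicity(img, mask):
    vals = [int(img[r][c]) for r in range(len(img)) for c in range(len(img[0])) if mask[r][c]]
    n = len(vals)
    lep = sum(1 for v in vals if v < 30) / n
    mep = sum(1 for v in vals if 50 <= v <= 150) / n
    hep = sum(1 for v in vals if v > 200) / n
    return lep, mep, hep


def brute_intensity_stats(img, mask):
    vals = [int(img[r][c]) for r in range(len(img)) for c in range(len(img[0])) if mask[r][c]]
    n = len(vals)
    mpi = sum(vals) / n
    piv = math.sqrt(sum((v - mpi) ** 2 for v in vals) / (n - 1)) if n > 1 else 0.0
    counts = {}
    for v in vals:
        counts[v] = counts.get(v, 0) + 1
    epi = -sum((c / n) * math.log2(c / n) for c in counts.values()) / 8.0
    return mpi, piv, epi


def brute_glcm(img, mask, offset):
    """Symmetric masked co-occurrence features for one (drow, dcol) offset.

    Returns None when no valid pixel pair exists.
    """
    dr, dc = offset
    h, w = len(img), len(img[0])
    pairs = []
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r][c] and mask[r2][c2]:
                pairs.append((int(img[r][c]), int(img[r2][c2])))
                pairs.append((int(img[r2][c2]), int(img[r][c])))  # symmetric
    if not pairs:
        return None
    n = len(pairs)
    p = {}
    for ij in pairs:
        p[ij] = p.get(ij, 0) + 1.0 / n
    contrast = sum(q * (i - j) ** 2 for (i, j), q in p.items())
    homogeneity = sum(q / (1.0 + (i - j) ** 2) for (i, j), q in p.items())
    energy = sum(q * q for q in p.values())
    mu_i = sum(q * i for (i, _), q in p.items())
    mu_j = sum(q * j for (_, j), q in p.items())
    sd_i = math.sqrt(sum(q * (i - mu_i) ** 2 for (i, _), q in p.items()))
    sd_j = math.sqrt(sum(q * (j - mu_j) ** 2 for (_, j), q in p.items()))
    if sd_i * sd_j == 0:
        corr = 0.0
    else:
        corr = sum(q * (i - mu_i) * (j - mu_j) for (i, j), q in p.items()) / (sd_i * sd_j)
    return dict(contrast=contrast, correlation=corr, energy=energy, homogeneity=homogeneity)


def brute_perimeter(mask):
    """Count exposed unit edges of the pixel-square union, one by one."""
    h, w = len(mask), len(mask[0])
    per = 0
    for r in range(h):
        for c in range(w):
            if not mask[r][c]:
                continue
            for r2, c2 in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if not (0 <= r2 < h and 0 <= c2 < w and mask[r2][c2]):
                    per += 1
    return float(per)


def shoelace(poly):
    s = 0.0
    for (x1, y1), (x2, y2) in zip(poly, poly[1:] + poly[:1]):
        s += x1 * y2 - x2 * y1
    return abs(s) / 2.0


# ---------------------------------------------------------------------------
# Exact rank-test null distributions (tie-free data)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def signed_rank_null(n: int) -> dict:
    """Counts of W+ over all 2^n sign assignments of ranks 1..n."""
    counts: dict = {}
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(rank for rank, s in zip(range(1, n + 1), signs) if s)
        counts[w] = counts.get(w, 0) + 1
    return counts


def wilcoxon_exact_p(d, alternative="two-sided") -> float:
    """Exact signed-rank p-value by full enumeration (requires no ties)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = int(ranks[d > 0].sum())
    null = signed_rank_null(n)
    total = 2**n
    p_le = sum(c for w, c in null.items() if w <= w_obs) / total
    p_ge = sum(c for w, c in null.items() if w >= w_obs) / total
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_le, p_ge))


@lru_cache(maxsize=None)
def mann_whitney_null(n1: int, n2: int) -> dict:
    """Counts of U1 over all C(n1+n2, n1) rank subsets."""
    counts: dict = {}
    ranks = range(1, n1 + n2 + 1)
    for subset in itertools.combinations(ranks, n1):
        u = sum(subset) - n1 * (n1 + 1) // 2
        counts[u] = counts.get(u, 0) + 1
    return counts


def mann_whitney_exact_p(a, b, alternative="two-sided") -> float:
    """Exact Mann-Whitney p-value by enumeration (requires no ties)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = int(ranks[: a.size].sum()) - a.size * (a.size + 1) // 2
    null = mann_whitney_null(a.size, b.size)
    total = math.comb(a.size + b.size, a.size)
    p_le = sum(c for u, c in null.items() if u <= u_obs) / total
    p_ge = sum(c for u, c in null.items() if u >= u_obs) / total
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_le, p_ge))


def random_mask(rng: np.random.Generator, max_side: int = 12, p: float = 0.5):
    """A random nonempty boolean mask with sides between 1 and max_side."""
    h = int(rng.integers(1, max_side + 1))
    w = int(rng.integers(1, max_side + 1))
    m = rng.random((h, w)) < p
    if not m.any():
        m[int(rng.integers(h)), int(rng.integers(w))] = True
    return m
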