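"""Independent brute-force reference implementations used only by tests.

Every function here re-derives its quantity from first principles (explicit
loops, pair enumeration, textbook constant formulas) without importing any
code path it is used to check.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np


def wc_fst_oracle(counts1: tuple[int, int, int], counts2: tuple[int, int, int]) -> float:
    """Weir & Cockerham (1984) theta-hat for two groups from genotype counts
    (n_AA, n_Aa, n_aa) per group, written in the generic r-population form."""
    groups = [counts1, counts2]
    r = len(groups)
    n = [sum(g) for g in groups]
    p = [(2 * g[0] + g[1]) / (2 * sum(g)) for g in groups]
    hfreq = [g[1] / sum(g) for g in groups]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, hfreq)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    return a / denom if denom != 0 else 0.0


def site_pi_oracle(alleles: list[int]) -> float:
    """Average pairwise difference at one site by explicit pair enumeration."""
    pairs = list(itertools.combinations(alleles, 2))
    if not pairs:
        return 0.0
    # the mean over unordered pairs of the mismatch indicator
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def tajimas_d_oracle(n: int, alt_counts: list[int]) -> float:
    """Tajima's D from textbook constants, explicit loops throughout."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    seg = [c for c in alt_counts if 0 < c < n]
    S = len(seg)
    if S == 0:
        return 0.0
    khat = sum(2.0 * c * (n - c) / (n * (n - 1)) for c in seg)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return 0.0
    return (khat - S / a1) / var**0.5


def h_stats_oracle(rows: list[tuple[int, ...]]) -> tuple[float, float]:
    """H1/H12 by counting haplotype strings with a Counter."""
    spectrum = Counter(rows)
    total = sum(spectrum.values())
    freqs = sorted((c / total for c in spectrum.values()), reverse=True)
    h1 = sum(f**2 for f in freqs)
    p1 = freqs[0]
    p2 = freqs[1] if len(freqs) > 1 else 0.0
    h12 = (p1 + p2) ** 2 + sum(f**2 for f in freqs[2:])
    return h1, h12


def rank_pvalue_oracle(values: list[float], tail: str) -> list[float]:
    """Fractional-rank p-values via explicit less-than / equal counting."""
    N = len(values)
    out = []
    for x in values:
        less = sum(1 for y in values if y < x)
        equal = sum(1 for y in values if y == x)
        rank = less + (equal + 1) / 2.0  # mean of the tied ascending ranks
        p = rank / (N + 1) if tail == "left" else (N + 1 - rank) / (N + 1)
        out.append(p)
    return out


def bh_oracle(p: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by double-loop step-up."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for k, i in enumerate(order, start=1):
        # min over all ranks j >= k of m * p_(j) / j
        q[i] = min(
            min(m * p[order[j - 1]] / j for j in range(k, m + 1)), 1.0
        )
    return q


def running_median_oracle(x: list[float], k: int) -> list[float]:
    """Centered window medians with constant ends, by explicit slicing."""
    n = len(x)
    if k >= n:
        return [float(np.median(x))] * n
    half = k // 2
    meds = [float(np.median(x[i - half: i + half + 1])) for i in range(half, n - half)]
    return [meds[0]] * half + meds + [meds[-1]] * half


def exhaustive_mcd_oracle(X: np.ndarray, h: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Raw MCD by enumerating every (n+1)-subset and concentrating each with
    its own C-step loop; returns (location, scatter, determinant) of the
    minimum-determinant non-singular h-subset (no consistency correction)."""
    N, n = X.shape
    best = None
    for comb in itertools.combinations(range(N), n + 1):
        cov0 = np.cov(X[list(comb)], rowvar=False, ddof=1)
        if np.linalg.det(np.atleast_2d(cov0)) <= 0:
            continue
        support = sorted(comb)
        for _ in range(500):
            mu = X[support].mean(axis=0)
            cov = np.atleast_2d(np.cov(X[support], rowvar=False, ddof=1))
            det = float(np.linalg.det(cov))
            if det <= 0:
                break
            d2 = [
                float((X[i] - mu) @ np.linalg.inv(cov) @ (X[i] - mu)) for i in range(N)
            ]
            new = sorted(sorted(range(N), key=lambda i: d2[i])[:h])
            if new == support:
                break
            support = new
        if det <= 0:
            continue
        if best is None or det < best[2]:
            best = (mu, cov, det)
    if best is None:
        raise ValueError("all subsets singular")
    return best
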