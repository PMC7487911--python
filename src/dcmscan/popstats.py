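"""Per-SNP population statistics: Weir-Cockerham FST, nucleotide diversity,
and binned Tajima's D, with the runmed-style smoothing used before combining.

FST contrasts one focal breed against all remaining samples pooled (two
groups). FST and pi are smoothed per chromosome with a running median of
width 31 and constant end rule; Tajima's D is computed in non-overlapping
physical bins and every SNP inherits its bin's value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import MISSING, GenioError, HaplotypePanel

STAT_NAMES = ("FST", "PI", "TAJD", "H1", "H12")

# one-tailed direction used when ranking each statistic into p-values:
# high FST/H1/H12 and low pi/D are sweep-like
STAT_TAILS = {"FST": "right", "PI": "left", "TAJD": "left", "H1": "right", "H12": "right"}


@dataclass
class StatTrack:
    """One per-SNP statistic vector aligned to a panel's variant order."""

    stat_name: str
    breed: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.stat_name not in STAT_NAMES:
            raise ValueError(f"unknown statistic {self.stat_name!r}")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.stat_name} track contains non-finite values")


def running_median(values: np.ndarray, k: int, endrule: str = "constant") -> np.ndarray:
    """Centered running median of odd width ``k`` with constant end rule.

    The first and last (k-1)//2 entries are set to the first and last
    computed window median (matching R's runmed endrule="constant").
    ``k`` wider than the vector collapses to the whole-vector median.
    """
    if k % 2 == 0 or k < 1:
        raise ValueError(f"window width k={k} must be odd and >= 1")
    if endrule != "constant":
        raise ValueError("only the constant end rule is supported")
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        return x.copy()
    if k >= n:
        return np.full(n, np.median(x))
    if k == 1:
        return x.copy()
    half = k // 2
    windows = np.lib.stride_tricks.sliding_window_view(x, k)
    med = np.median(windows, axis=1)
    out = np.empty(n)
    out[half:n - half] = med
    out[:half] = med[0]
    out[n - half:] = med[-1]
    return out


def _smooth_per_chrom(panel: HaplotypePanel, values: np.ndarray, k: int) -> np.ndarray:
    out = np.empty_like(values)
    for sl in panel.chrom_slices().values():
        out[sl] = running_median(values[sl], k)
    return out


def _group_counts(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n diploids called, alt allele freq, het frequency) per SNP for one
    group's dosage matrix."""
    called = g != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.sum(np.where(called, g, 0), axis=0) / (2 * n), 0.0)
        h = np.where(n > 0, np.sum(g == 1, axis=0) / n, 0.0)
    return n, p, h


def wc_fst_components(
    n1: float, p1: float, h1: float, n2: float, p2: float, h2: float
) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components (a, b, c) for two groups
    at one biallelic SNP, from per-group diploid sample sizes, alt-allele
    frequencies and observed heterozygote frequencies."""
    r = 2.0
    nbar = (n1 + n2) / r
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def wc_fst_per_snp(
    panel: HaplotypePanel, focal_pop: str, smooth_k: int = 31
) -> StatTrack:
    """Per-SNP Weir-Cockerham FST (theta-hat) of one breed against the pooled
    rest, negatives clipped to 0, then smoothed per chromosome.

    SNPs where either group has fewer than 2 called diploid genotypes get 0.
    """
    focal_idx = panel.sample_indices(focal_pop)
    rest_idx = np.setdiff1d(np.arange(panel.n_samples), focal_idx)
    if rest_idx.size == 0:
        raise GenioError("FST needs at least one non-focal sample")
    g = panel.genotypes()
    n1, p1, h1 = _group_counts(g[focal_idx])
    n2, p2, h2 = _group_counts(g[rest_idx])

    raw = np.zeros(panel.n_variants)
    ok = (n1 >= 2) & (n2 >= 2)
    for j in np.flatnonzero(ok):
        a, b, c = wc_fst_components(n1[j], p1[j], h1[j], n2[j], p2[j], h2[j])
        denom = a + b + c
        raw[j] = a / denom if denom != 0.0 else 0.0
    raw = np.clip(raw, 0.0, None)
    if smooth_k > 1:
        raw = _smooth_per_chrom(panel, raw, smooth_k)
    return StatTrack("FST", focal_pop, raw)


def _allele_counts(panel: HaplotypePanel, pop: str) -> tuple[np.ndarray, np.ndarray]:
    """(non-missing chromosome count, alt allele count) per SNP within pop."""
    Hp = panel.H[panel.hap_rows(pop)]
    called = Hp != MISSING
    n = called.sum(axis=0).astype(float)
    c1 = np.sum(Hp == 1, axis=0).astype(float)
    return n, c1


def site_pi_values(n: np.ndarray, c1: np.ndarray) -> np.ndarray:
    """Per-site nucleotide diversity 2*c0*c1 / (n*(n-1)); 0 when n < 2."""
    c0 = n - c1
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, 2.0 * c0 * c1 / (n * (n - 1.0)), 0.0)
    return pi


def site_pi(panel: HaplotypePanel, pop: str, smooth_k: int = 31) -> StatTrack:
    """Per-site pi within one breed, smoothed per chromosome (running median,
    constant ends)."""
    n, c1 = _allele_counts(panel, pop)
    pi = site_pi_values(n, c1)
    if smooth_k > 1:
        pi = _smooth_per_chrom(panel, pi, smooth_k)
    return StatTrack("PI", pop, pi)


def tajima_constants(n: int) -> dict[str, float]:
    """The a1, a2, b1, b2, c1, c2, e1, e2 normalizing constants of Tajima's D
    for ``n`` sampled chromosomes."""
    if n < 2:
        raise ValueError("Tajima's D needs >= 2 chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(n: int, alt_counts: np.ndarray) -> float:
    """Tajima's D for one bin: ``n`` chromosomes, per-site alt allele counts.

    Sites that are monomorphic (count 0 or n) contribute nothing. Returns 0
    when there are no segregating sites or the variance term is degenerate.
    """
    ac = np.asarray(alt_counts, dtype=float)
    seg = (ac > 0) & (ac < n)
    S = int(seg.sum())
    if S == 0:
        return 0.0
    c1 = ac[seg]
    c0 = n - c1
    khat = float(np.sum(2.0 * c0 * c1 / (n * (n - 1.0))))
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1.0)
    if var <= 0.0:
        return 0.0
    return (khat - S / k["a1"]) / np.sqrt(var)


def tajimas_d_per_snp(
    panel: HaplotypePanel, pop: str, bin_bp: int = 300_000
) -> StatTrack:
    """Tajima's D in non-overlapping physical bins, assigned to every SNP of
    the bin; bins with no segregating sites (or undefined variance) get 0.

    The bin partition is [0, bin_bp), [bin_bp, 2*bin_bp), ... per chromosome.
    The sample-size constants use the modal non-missing chromosome count
    across the bin's sites.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    n_chroms, c1 = _allele_counts(panel, pop)
    out = np.zeros(panel.n_variants)
    pos = panel.positions
    for sl in panel.chrom_slices().values():
        bins = pos[sl] // bin_bp
        idx0 = sl.start
        for b in np.unique(bins):
            in_bin = np.flatnonzero(bins == b) + idx0
            nn = n_chroms[in_bin]
            nn = nn[nn >= 2]
            if nn.size == 0:
                continue
            # modal non-missing chromosome count across the bin's sites
            uniq, cnt = np.unique(nn, return_counts=True)
            n_mode = int(uniq[np.argmax(cnt)])
            usable = in_bin[n_chroms[in_bin] == n_mode]
            out[in_bin] = tajimas_d(n_mode, c1[usable])
    return StatTrack("TAJD", pop, out)
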