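"""Garud's H1 and H12 haplotype-homozygosity statistics in sliding windows.

For a window of consecutive SNPs with distinct-haplotype frequencies
p1 >= p2 >= ...:

    H1  = sum_i p_i^2
    H12 = (p1 + p2)^2 + sum_{i>=3} p_i^2 = H1 + 2*p1*p2

H12 pools the two most frequent haplotypes, which boosts power when a sweep
has split the sweeping haplotype (soft or interrupted hard sweeps). Windows
slide one SNP at a time within each chromosome; each window's value is
anchored to its center SNP so the tracks align per-SNP with FST/pi/D.
"""

from __future__ import annotations

import numpy as np

from .genio import MISSING, GenioError, HaplotypePanel
from .popstats import StatTrack


def haplotype_spectrum(window: np.ndarray) -> np.ndarray:
    """Frequencies (descending) of distinct haplotypes in a (haps x snps)
    allele-code window; haplotypes containing missing calls are dropped and
    frequencies renormalized over the rest."""
    keep = ~np.any(window == MISSING, axis=1)
    rows = np.ascontiguousarray(window[keep])
    if rows.shape[0] == 0:
        return np.array([])
    void = rows.view(np.dtype((np.void, rows.dtype.itemsize * rows.shape[1])))
    _, counts = np.unique(void.ravel(), return_counts=True)
    freqs = np.sort(counts / counts.sum())[::-1]
    return freqs


def h1_h12_from_spectrum(freqs: np.ndarray) -> tuple[float, float]:
    """H1 and H12 from a descending haplotype-frequency spectrum."""
    if freqs.size == 0:
        return np.nan, np.nan
    h1 = float(np.sum(freqs**2))
    p1 = float(freqs[0])
    p2 = float(freqs[1]) if freqs.size > 1 else 0.0
    return h1, h1 + 2.0 * p1 * p2


def window_h_stats(
    panel: HaplotypePanel,
    pop: str,
    window: int = 14,
    step: int = 1,
) -> tuple[StatTrack, StatTrack]:
    """H1 and H12 per SNP for one population.

    Windows of ``window`` consecutive SNPs advance by ``step`` within each
    chromosome. A window's value is assigned to its ceil(window/2)-th SNP;
    chromosome-end SNPs without an assigned window take the nearest assigned
    value (constant extension). A chromosome with fewer SNPs than ``window``
    raises.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    Hp = panel.H[panel.hap_rows(pop)]
    n_snps = panel.n_variants
    h1 = np.full(n_snps, np.nan)
    h12 = np.full(n_snps, np.nan)
    anchor_off = int(np.ceil(window / 2)) - 1
    for chrom, sl in panel.chrom_slices().items():
        m = sl.stop - sl.start
        if m < window:
            raise GenioError(
                f"chromosome {chrom} shorter than window ({m} < {window})"
            )
        for start in range(0, m - window + 1, step):
            freqs = haplotype_spectrum(Hp[:, sl.start + start: sl.start + start + window])
            a, b = h1_h12_from_spectrum(freqs)
            h1[sl.start + start + anchor_off] = a
            h12[sl.start + start + anchor_off] = b
        _constant_extend(h1, sl)
        _constant_extend(h12, sl)
    return StatTrack("H1", pop, h1), StatTrack("H12", pop, h12)


def _constant_extend(values: np.ndarray, sl: slice) -> None:
    """Fill NaN runs at the chromosome edges (and any interior gaps left by
    step > 1) with the nearest assigned value."""
    seg = values[sl.start: sl.stop]
    assigned = np.flatnonzero(~np.isnan(seg))
    if assigned.size == 0:
        raise GenioError("no haplotype window could be assigned")
    missing = np.flatnonzero(np.isnan(seg))
    if missing.size:
        nearest = assigned[np.abs(missing[:, None] - assigned[None, :]).argmin(axis=1)]
        seg[missing] = seg[nearest]
    values[sl.start: sl.stop] = seg
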