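"""Candidate-region calling from per-SNP q-values and gene annotation.

A region is seeded by a run of at least ``min_seed`` consecutive SNPs with
q below the significance level (default 0.05) and extended outward over
flanking SNPs whose q stays at or below a looser level (default 0.1); the
first flanking SNP above the looser level is excluded. Touching or
overlapping extensions merge. Genes overlapping a region are ranked by
distance from its most significant (peak) SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GeneSet


@dataclass
class Region:
    """A called significant interval (1-based inclusive, single chromosome)."""

    breed: str
    region_id: str
    chrom: str
    start: int
    end: int
    n_sig_snps: int
    peak_pos: int
    peak_q: float

    def __post_init__(self) -> None:
        if not self.start <= self.peak_pos <= self.end:
            raise ValueError("peak must lie inside the region")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneHit:
    """A gene overlapping a region; rank 1 = closest to the peak SNP."""

    region_id: str
    gene_id: str
    distance_bp: int
    rank: int


def call_regions(
    pos: np.ndarray,
    q: np.ndarray,
    chrom: str = "1",
    breed: str = "pop",
    sig: float = 0.05,
    ext: float = 0.1,
    min_seed: int = 2,
    include_flank: bool = False,
    region_offset: int = 0,
) -> list[Region]:
    """Call candidate regions on one chromosome from sorted (pos, q) pairs.

    ``include_flank=True`` selects the alternative boundary convention in
    which the first flanking SNP above ``ext`` is itself included.
    ``region_offset`` shifts region numbering so that ids stay unique when
    the caller concatenates chromosomes.
    """
    pos = np.asarray(pos)
    q = np.asarray(q, dtype=float)
    if pos.shape != q.shape:
        raise ValueError("pos and q must be equally long")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q-values must lie in [0, 1]")
    n = pos.size

    sig_mask = q < sig
    # maximal runs of consecutive significant SNPs
    spans: list[tuple[int, int]] = []  # inclusive index spans after extension
    i = 0
    while i < n:
        if not sig_mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig_mask[j + 1]:
            j += 1
        if j - i + 1 >= min_seed:
            lo, hi = i, j
            while lo - 1 >= 0 and q[lo - 1] <= ext:
                lo -= 1
            while hi + 1 < n and q[hi + 1] <= ext:
                hi += 1
            if include_flank:
                lo = max(lo - 1, 0)
                hi = min(hi + 1, n - 1)
            spans.append((lo, hi))
        i = j + 1

    # merge spans that touch or overlap
    merged: list[list[int]] = []
    for lo, hi in spans:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])

    regions: list[Region] = []
    for k, (lo, hi) in enumerate(merged):
        qq = q[lo: hi + 1]
        peak_rel = int(np.argmin(qq))
        regions.append(
            Region(
                breed=breed,
                region_id=f"{breed}_r{region_offset + k + 1}",
                chrom=chrom,
                start=int(pos[lo]),
                end=int(pos[hi]),
                n_sig_snps=int(np.sum(qq < sig)),
                peak_pos=int(pos[lo + peak_rel]),
                peak_q=float(qq[peak_rel]),
            )
        )
    return regions


def annotate_regions(regions: list[Region], genes: GeneSet) -> list[GeneHit]:
    """Genes overlapping each region, ranked by distance from the peak SNP.

    Distance is from the peak SNP to the nearest gene edge (0 when the peak
    lies inside the gene); ties are broken by genomic start. Chromosome
    labels of the regions must all occur in the gene set.
    """
    gene_chroms = set(genes.records["chrom"].astype(str))
    unmatched = sorted({r.chrom for r in regions} - gene_chroms)
    if unmatched:
        raise ValueError(
            f"region chromosomes absent from gene models: {unmatched}"
        )
    hits: list[GeneHit] = []
    for r in regions:
        sub = genes.records[
            (genes.records["chrom"].astype(str) == r.chrom)
            & (genes.records["start"] <= r.end)
            & (genes.records["end"] >= r.start)
        ]
        if sub.empty:
            continue
        dist = np.where(
            (sub["start"] <= r.peak_pos) & (sub["end"] >= r.peak_pos),
            0,
            np.minimum(
                np.abs(sub["start"] - r.peak_pos), np.abs(sub["end"] - r.peak_pos)
            ),
        )
        order = np.lexsort((sub["start"].to_numpy(), dist))
        for rank, o in enumerate(order, start=1):
            hits.append(
                GeneHit(
                    region_id=r.region_id,
                    gene_id=str(sub["gene_id"].iloc[o]),
                    distance_bp=int(dist[o]),
                    rank=rank,
                )
            )
    return hits


def summarize_regions(regions: list[Region]) -> pd.DataFrame:
    """Per-breed descriptive table: region count, mean +/- SD length (kb),
    significant-SNP count, total length (Mb)."""
    cols = ["breed", "n_regions", "mean_kb", "sd_kb", "n_snps", "total_mb"]
    if not regions:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(
        {
            "breed": [r.breed for r in regions],
            "length": [r.length_bp for r in regions],
            "n_snps": [r.n_sig_snps for r in regions],
        }
    )
    rows = []
    for breed, sub in df.groupby("breed", sort=True):
        rows.append(
            dict(
                breed=breed,
                n_regions=len(sub),
                mean_kb=sub["length"].mean() / 1e3,
                sd_kb=sub["length"].std(ddof=1) / 1e3 if len(sub) > 1 else 0.0,
                n_snps=int(sub["n_snps"].sum()),
                total_mb=sub["length"].sum() / 1e6,
            )
        )
    return pd.DataFrame(rows, columns=cols)
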