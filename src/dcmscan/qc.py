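"""SNP/sample quality control, panel merging, and IBS-based PCA outliers.

Filters mirror standard array QC: drop duplicated / sex-chromosome / unplaced
markers, low call-rate samples, then low call-rate, low-MAF and
HWE-departing SNPs. The per-criterion tallies are reported so that
``retained + removed`` always reconciles with the input.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .genio import MISSING, GenioError, HaplotypePanel


@dataclass(frozen=True)
class QcThresholds:
    """Marker/sample retention thresholds (fractions in [0, 1])."""

    snp_call_rate: float = 0.95
    maf: float = 0.05
    hwe_p: float = 1e-6
    sample_call_rate: float = 0.95

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    """Counts removed per criterion, in the order the filters run."""

    n_snps_in: int = 0
    n_samples_in: int = 0
    duplicate_removed: int = 0
    sex_unplaced_removed: int = 0
    sample_call_rate_removed: int = 0
    snp_call_rate_removed: int = 0
    maf_removed: int = 0
    hwe_removed: int = 0
    n_snps_out: int = 0
    n_samples_out: int = 0
    filter_order: tuple[str, ...] = (
        "duplicate/sex/unplaced", "sample_call_rate",
        "snp_call_rate", "maf", "hwe",
    )

    def to_dict(self) -> dict:
        return asdict(self)


def hwe_chisq_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square goodness-of-fit p-value for Hardy-Weinberg proportions.

    Expected genotype counts are formed at the sample allele frequency;
    monomorphic input returns 1 (no test possible, chi-square 0).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def _snp_stats(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (call_rate, maf, hwe_p) from a dosage matrix (samples x snps)."""
    n_samples = g.shape[0]
    called = g != MISSING
    n_called = called.sum(axis=0)
    call_rate = n_called / n_samples
    n_aa = np.sum((g == 0) & called, axis=0)
    n_het = np.sum(g == 1, axis=0)
    n_AA = np.sum(g == 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_called > 0, (2 * n_AA + n_het) / (2 * n_called), 0.0)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    hwe_p = np.array(
        [
            hwe_chisq_pvalue(int(a), int(h), int(c)) if (a + h + c) > 0 else 1.0
            for a, h, c in zip(n_AA, n_het, n_aa)
        ]
    )
    return call_rate, maf, hwe_p


def filter_panel(
    panel: HaplotypePanel,
    thr: QcThresholds = QcThresholds(),
    sex_chroms: set[str] | frozenset[str] = frozenset({"X", "Y"}),
    unplaced_chroms: set[str] | frozenset[str] = frozenset({"0", "Un", "."}),
) -> tuple[HaplotypePanel, QcReport]:
    """Apply the fixed-order QC cascade and tally removals per criterion.

    Order: duplicated-id / sex-chromosome / unplaced markers, then sample
    call rate, then SNP call rate, MAF (on non-missing alleles) and the
    HWE chi-square test. Raises if no SNP survives.
    """
    rep = QcReport(n_snps_in=panel.n_variants, n_samples_in=panel.n_samples)

    # 1. duplicates / sex / unplaced
    ids = panel.variants["id"]
    dup = ids.duplicated(keep="first").to_numpy()
    sexun = panel.variants["chrom"].isin(set(sex_chroms) | set(unplaced_chroms))
    sexun = sexun.to_numpy()
    rep.duplicate_removed = int(dup.sum())
    rep.sex_unplaced_removed = int((sexun & ~dup).sum())
    keep_v = ~(dup | sexun)
    panel = panel.take_variants(np.flatnonzero(keep_v))
    if panel.n_variants == 0:
        raise GenioError("empty panel: all SNPs removed by QC")

    # 2. sample call rate
    g = panel.genotypes()
    s_rate = np.mean(g != MISSING, axis=1)
    keep_s = s_rate >= thr.sample_call_rate
    rep.sample_call_rate_removed = int(np.sum(~keep_s))
    if not keep_s.all():
        panel = panel.take_samples(np.flatnonzero(keep_s))
        g = panel.genotypes()

    # 3-5. SNP call rate, MAF, HWE — each tallied against the survivors of
    # the previous step.
    call_rate, maf, hwe_p = _snp_stats(g)
    fail_cr = call_rate < thr.snp_call_rate
    fail_maf = ~fail_cr & (maf < thr.maf)
    fail_hwe = ~fail_cr & ~fail_maf & (hwe_p < thr.hwe_p)
    rep.snp_call_rate_removed = int(fail_cr.sum())
    rep.maf_removed = int(fail_maf.sum())
    rep.hwe_removed = int(fail_hwe.sum())
    keep = ~(fail_cr | fail_maf | fail_hwe)
    if not keep.any():
        raise GenioError("empty panel: all SNPs removed by QC")
    panel = panel.take_variants(np.flatnonzero(keep))
    rep.n_snps_out = panel.n_variants
    rep.n_samples_out = panel.n_samples
    return panel, rep


def merge_panels(a: HaplotypePanel, b: HaplotypePanel) -> HaplotypePanel:
    """Merge two panels on their mutual SNPs, concatenating samples.

    Variants are intersected by (chrom, pos, id); ref/alt must match either
    directly or after reverse-complementing both alleles (strand-safe check).
    Variant order follows panel ``a``.
    """
    from .genio import _revcomp_allele

    if set(a.samples) & set(b.samples):
        raise GenioError("merge requires disjoint sample sets")
    key_b = {
        (r.chrom, r.pos, r.id): (i, r.ref, r.alt)
        for i, r in enumerate(b.variants.itertuples(index=False))
    }
    idx_a: list[int] = []
    idx_b: list[int] = []
    for i, r in enumerate(a.variants.itertuples(index=False)):
        hit = key_b.get((r.chrom, r.pos, r.id))
        if hit is None:
            continue
        j, ref_b, alt_b = hit
        same = (r.ref, r.alt) == (ref_b, alt_b)
        flipped = (_revcomp_allele(r.ref), _revcomp_allele(r.alt)) == (ref_b, alt_b)
        if not (same or flipped):
            raise GenioError(
                f"allele mismatch at shared SNP {r.id!r}: "
                f"{r.ref}/{r.alt} vs {ref_b}/{alt_b}"
            )
        idx_a.append(i)
        idx_b.append(j)
    if not idx_a:
        raise GenioError("no mutual SNPs between panels")
    pa = a.take_variants(idx_a)
    pb = b.take_variants(idx_b)
    return HaplotypePanel(
        variants=pa.variants,
        samples=pa.samples + pb.samples,
        pops=pa.pops + pb.pops,
        H=np.vstack([pa.H, pb.H]),
        phased=a.phased and b.phased,
    )


def ibs_matrix(panel: HaplotypePanel) -> np.ndarray:
    """Pairwise identity-by-state matrix: mean shared-allele fraction.

    Entry (i, j) averages, over jointly non-missing SNPs, the number of
    alleles the two diploid genotypes share (0, 1 or 2) divided by 2.
    Diagonal is 1.
    """
    if panel.n_samples < 2:
        raise GenioError("IBS matrix requires at least 2 samples")
    g = panel.genotypes().astype(np.float64)
    miss = g == MISSING
    g[miss] = np.nan
    n = panel.n_samples
    out = np.ones((n, n))
    for i in range(n):
        diff = np.abs(g[i] - g[i + 1:])  # NaN where either missing
        valid = ~np.isnan(diff)
        n_valid = valid.sum(axis=1)
        if np.any(n_valid == 0):
            j = i + 1 + int(np.argmax(n_valid == 0))
            raise GenioError(
                f"samples {panel.samples[i]!r} and {panel.samples[j]!r} share "
                "no jointly called SNP"
            )
        share = np.nansum(2.0 - diff, axis=1) / (2.0 * n_valid)
        out[i, i + 1:] = share
        out[i + 1:, i] = share
    return out


def pca_from_ibs(
    ibs: np.ndarray,
    n_components: int = 10,
    pops: list[str] | None = None,
    outlier_z: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of an IBS similarity matrix, with per-population outlier flags.

    The matrix is double-centered (so adding a constant changes nothing) and
    eigen-decomposed; coordinates are eigenvectors scaled by sqrt(eigenvalue).
    A sample is flagged when, on PC1 or PC2, it lies more than ``outlier_z``
    robust standard deviations (1.4826 * MAD) from its population's median.

    Returns (coordinates [n x k], eigenvalues [k], outlier flags [n]).
    """
    ibs = np.asarray(ibs, dtype=float)
    if ibs.ndim != 2 or ibs.shape[0] != ibs.shape[1]:
        raise ValueError("IBS matrix must be square")
    if not np.allclose(ibs, ibs.T, atol=1e-8):
        raise ValueError("IBS matrix must be symmetric")
    n = ibs.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    centered = J @ ibs @ J
    evals, evecs = np.linalg.eigh(centered)
    order = np.argsort(evals)[::-1]
    k = min(n_components, n)
    evals = np.clip(evals[order][:k], 0.0, None)
    coords = evecs[:, order][:, :k] * np.sqrt(evals)

    flags = np.zeros(n, dtype=bool)
    if pops is not None:
        pops_arr = np.asarray(pops)
        npc = min(2, k)
        for pop in np.unique(pops_arr):
            idx = np.flatnonzero(pops_arr == pop)
            for c in range(npc):
                x = coords[idx, c]
                center = np.median(x)
                mad = np.median(np.abs(x - center))
                sd = 1.4826 * mad
                if sd == 0.0:
                    sd = float(np.std(x))
                if sd == 0.0:
                    continue
                flags[idx] |= np.abs(x - center) > outlier_z * sd
    return coords, evals, flags
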