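"""I/O and core containers: phased haplotype panels, gene models, result tables.

All genomic coordinates held in memory are 1-based inclusive (VCF convention).
BED input/output is converted at the boundary. Genotype panels are biallelic
only; allele codes are 0 (ref), 1 (alt) and ``MISSING`` (-1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


class GenioError(ValueError):
    """Raised on malformed or contract-violating genomic input."""


def _revcomp_allele(a: str) -> str:
    return a.translate(_COMPLEMENT)


@dataclass(frozen=True)
class VariantMeta:
    """One biallelic SNP: chromosome, 1-based position, id, ref/alt alleles."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise GenioError(f"variant {self.id}: position {self.pos} < 1")


@dataclass
class HaplotypePanel:
    """Phased haplotype matrix with aligned variant metadata.

    Attributes
    ----------
    variants : pandas.DataFrame
        Columns ``chrom, pos, id, ref, alt``, one row per SNP, ordered per
        chromosome by increasing position.
    samples : list of str
        Sample identifiers, in column-pair order of ``H``.
    pops : list of str
        Population/breed label per sample (parallel to ``samples``).
    H : numpy.ndarray of int8, shape (2 * n_samples, n_variants)
        Allele codes; rows 2i and 2i+1 are the two haplotypes of sample i.
    phased : bool
        Whether the genotypes were phased in the source.
    """

    variants: pd.DataFrame
    samples: list[str]
    pops: list[str]
    H: np.ndarray
    phased: bool = True

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=np.int8)
        self.variants = self.variants.reset_index(drop=True)
        if self.H.shape != (2 * len(self.samples), len(self.variants)):
            raise GenioError(
                f"haplotype matrix shape {self.H.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(self.pops) != len(self.samples):
            raise GenioError("pops and samples must have equal length")
        bad = ~np.isin(self.H, (0, 1, MISSING))
        if bad.any():
            raise GenioError("allele codes must be 0, 1 or missing (-1)")
        self._check_sorted()

    def _check_sorted(self) -> None:
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                i = int(np.argmax(np.diff(pos) <= 0))
                raise GenioError(
                    f"non-monotonic positions on chromosome {chrom} near "
                    f"record {sub['id'].iloc[i + 1]!r}"
                )

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return self.variants["pos"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.variants["chrom"].to_numpy()

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous variant-index slice per chromosome, in panel order."""
        out: dict[str, slice] = {}
        chroms = self.variants["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[str(chroms[start])] = slice(start, i)
                start = i
        return out

    # -- genotype views ----------------------------------------------------
    def genotypes(self) -> np.ndarray:
        """Diploid dosage matrix (n_samples x n_variants): 0/1/2, MISSING if
        either haplotype allele is missing."""
        a = self.H[0::2].astype(np.int16)
        b = self.H[1::2].astype(np.int16)
        g = a + b
        g[(a == MISSING) | (b == MISSING)] = MISSING
        return g

    def sample_indices(self, pop: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.pops) == pop)
        if idx.size == 0:
            raise GenioError(f"population label {pop!r} not present in panel")
        return idx

    def hap_rows(self, pop: str) -> np.ndarray:
        """Haplotype rows (2 per sample) belonging to one population."""
        s = self.sample_indices(pop)
        return np.ravel(np.column_stack((2 * s, 2 * s + 1)))

    # -- subsetting --------------------------------------------------------
    def take_variants(self, index: np.ndarray | Sequence[int]) -> "HaplotypePanel":
        index = np.asarray(index, dtype=int)
        return HaplotypePanel(
            variants=self.variants.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
            pops=list(self.pops),
            H=self.H[:, index].copy(),
            phased=self.phased,
        )

    def take_samples(self, index: np.ndarray | Sequence[int]) -> "HaplotypePanel":
        index = np.asarray(index, dtype=int)
        rows = np.ravel(np.column_stack((2 * index, 2 * index + 1)))
        return HaplotypePanel(
            variants=self.variants.copy(),
            samples=[self.samples[i] for i in index],
            pops=[self.pops[i] for i in index],
            H=self.H[rows].copy(),
            phased=self.phased,
        )

    def equals(self, other: "HaplotypePanel") -> bool:
        return (
            self.samples == other.samples
            and self.pops == other.pops
            and self.variants.reset_index(drop=True).equals(
                other.variants.reset_index(drop=True)
            )
            and np.array_equal(self.H, other.H)
        )


@dataclass
class GeneSet:
    """Gene models as a table of (gene_id, chrom, start, end, biotype),
    coordinates 1-based inclusive."""

    records: pd.DataFrame

    COLUMNS = ["gene_id", "chrom", "start", "end", "biotype"]

    def __post_init__(self) -> None:
        self.records = self.records[self.COLUMNS].reset_index(drop=True)
        bad = self.records["start"] > self.records["end"]
        if bad.any():
            g = self.records.loc[bad, "gene_id"].iloc[0]
            raise GenioError(f"gene {g!r}: start > end")

    def protein_coding(self) -> "GeneSet":
        keep = self.records["biotype"] == "protein_coding"
        return GeneSet(self.records[keep].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(
    path: str | Path,
    pop_labels: Mapping[str, str] | None = None,
    allow_unphased: bool = False,
) -> HaplotypePanel:
    """Read a phased VCF into a :class:`HaplotypePanel`.

    Parameters
    ----------
    path : path to an (optionally bgzipped) VCF with GT.
    pop_labels : map sample id -> population label. Samples absent from the
        map get population label ``"pop"``.
    allow_unphased : if True, "/"-separated genotypes are accepted and their
        alleles taken in written order; otherwise they raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise GenioError(f"{path}: VCF contains no samples / GT field")
    pops = [(pop_labels or {}).get(s, "pop") for s in samples]

    rows: list[tuple[str, int, str, str, str]] = []
    haps: list[np.ndarray] = []
    seen_ids: set[str] = set()
    last: dict[str, int] = {}
    for v in vcf:
        if len(v.ALT) != 1:
            raise GenioError(
                f"record {v.ID or v.POS} is not biallelic (ALT={v.ALT})"
            )
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        if vid in seen_ids:
            raise GenioError(f"duplicated variant id {vid!r}")
        seen_ids.add(vid)
        if v.CHROM in last and v.POS <= last[v.CHROM]:
            raise GenioError(
                f"non-monotonic position at record {vid!r} "
                f"({v.CHROM}:{v.POS} after {last[v.CHROM]})"
            )
        last[v.CHROM] = v.POS
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):  # [a, b, phased]
            a, b, ph = gt[0], gt[1], bool(gt[2])
            if not ph and not allow_unphased and not (a < 0 and b < 0):
                raise GenioError(
                    f"unphased genotype for sample {samples[i]!r} at {vid!r}"
                )
            col[2 * i] = a if a >= 0 else MISSING
            col[2 * i + 1] = b if b >= 0 else MISSING
        rows.append((v.CHROM, v.POS, vid, v.REF, v.ALT[0]))
        haps.append(col)
    if not rows:
        raise GenioError(f"{path}: no variant records")
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    H = np.stack(haps, axis=1).astype(np.int8)
    return HaplotypePanel(variants=variants, samples=samples, pops=pops, H=H)


def write_phased_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel as an uncompressed VCF 4.2 with phased GT."""
    path = Path(path)
    sep = "|" if panel.phased else "/"
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(panel.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        H = panel.H
        for j, row in enumerate(panel.variants.itertuples(index=False)):
            gts = []
            for i in range(panel.n_samples):
                a, b = H[2 * i, j], H[2 * i + 1, j]
                sa = "." if a == MISSING else str(int(a))
                sb = "." if b == MISSING else str(int(b))
                gts.append(f"{sa}{sep}{sb}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gene_models(
    path: str | Path,
    format: str = "BED",
    protein_coding_only: bool = False,
) -> GeneSet:
    """Read gene models from BED4+ (0-based half-open, optional 5th column
    biotype) or GFF3 ``gene`` features (1-based inclusive) into a GeneSet."""
    path = Path(path)
    fmt = format.upper()
    recs: list[tuple[str, str, int, int, str]] = []
    if fmt == "BED":
        with path.open() as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise GenioError(f"{path}:{ln}: BED line has < 4 fields")
                try:
                    start0, end0 = int(f[1]), int(f[2])
                except ValueError as e:
                    raise GenioError(f"{path}:{ln}: non-integer coordinate") from e
                if start0 < 0 or start0 >= end0:
                    raise GenioError(
                        f"{path}:{ln}: invalid BED interval [{start0}, {end0})"
                    )
                biotype = f[4] if len(f) > 4 and f[4] not in (".", "") else ""
                recs.append((f[3], f[0], start0 + 1, end0, biotype))
    elif fmt == "GFF3":
        with path.open() as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) != 9:
                    raise GenioError(f"{path}:{ln}: GFF3 line has {len(f)} fields")
                if f[2] != "gene":
                    continue
                try:
                    start, end = int(f[3]), int(f[4])
                except ValueError as e:
                    raise GenioError(f"{path}:{ln}: non-integer coordinate") from e
                if start > end or start < 1:
                    raise GenioError(f"{path}:{ln}: invalid interval {start}-{end}")
                attrs = _parse_gff3_attributes(f[8])
                gid = attrs.get("gene_id") or attrs.get("Name") or attrs.get("ID")
                if gid is None:
                    raise GenioError(f"{path}:{ln}: gene feature without an id")
                biotype = attrs.get("biotype") or attrs.get("gene_biotype") or ""
                recs.append((gid, f[0], start, end, biotype))
    else:
        raise GenioError(f"unknown gene model format {format!r}")
    df = pd.DataFrame(recs, columns=GeneSet.COLUMNS)
    gs = GeneSet(df)
    if protein_coding_only:
        gs = gs.protein_coding()
    return gs


def write_gene_bed(genes: GeneSet, path: str | Path) -> None:
    """Write a GeneSet as BED4+1 (chrom, 0-based start, end, gene_id, biotype)."""
    with Path(path).open("w") as fh:
        for r in genes.records.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene_id}\t"
                f"{r.biotype or '.'}\n"
            )


# ---------------------------------------------------------------------------
# Region / gene-hit tables
# ---------------------------------------------------------------------------

REGION_HEADER = [
    "breed", "region_id", "chrom", "start", "end",
    "n_snps", "peak_pos", "peak_q", "row_type", "gene_id", "distance_bp", "rank",
]


def write_region_table(regions: Iterable, hits: Iterable, path: str | Path) -> None:
    """Write called regions and their gene hits as one TSV.

    One ``region`` row per region followed by one ``gene`` row per annotated
    gene (rank 1 = closest to the peak SNP). Empty input yields a header-only
    file; the table round-trips through :func:`read_region_table`.
    """
    hit_by_region: dict[str, list] = {}
    for h in hits:
        hit_by_region.setdefault(h.region_id, []).append(h)
    rows: list[dict] = []
    for r in regions:
        rows.append(
            dict(
                breed=r.breed, region_id=r.region_id, chrom=r.chrom,
                start=r.start, end=r.end, n_snps=r.n_sig_snps,
                peak_pos=r.peak_pos, peak_q=r.peak_q, row_type="region",
                gene_id="", distance_bp="", rank="",
            )
        )
        for h in sorted(hit_by_region.get(r.region_id, []), key=lambda x: x.rank):
            rows.append(
                dict(
                    breed=r.breed, region_id=r.region_id, chrom=r.chrom,
                    start=r.start, end=r.end, n_snps=r.n_sig_snps,
                    peak_pos=r.peak_pos, peak_q=r.peak_q, row_type="gene",
                    gene_id=h.gene_id, distance_bp=h.distance_bp, rank=h.rank,
                )
            )
    df = pd.DataFrame(rows, columns=REGION_HEADER)
    df.to_csv(path, sep="\t", index=False)


def read_region_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "breed": str})
    missing = [c for c in REGION_HEADER if c not in df.columns]
    if missing:
        raise GenioError(f"{path}: missing columns {missing}")
    return df


def write_run_report(report: Mapping, path: str | Path) -> None:
    """Serialize a run report (filter tallies, fitted parameters, ...) as JSON."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"unserializable {type(o)}")

    with Path(path).open("w") as fh:
        json.dump(report, fh, indent=2, default=_default)
        fh.write("\n")
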