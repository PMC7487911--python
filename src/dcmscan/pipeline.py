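"""End-to-end scan orchestration: QC -> five tracks -> DCMS -> regions.

`run_scan` is a pure function of (inputs, configuration, seeds): given the
same configuration it writes byte-identical outputs. One master seed fans
out to named child seeds (simulation, per-breed MCD) so each stage is
independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composite import dcms_from_tracks
from .genio import (
    GeneSet,
    HaplotypePanel,
    read_gene_models,
    read_phased_vcf,
    write_region_table,
    write_run_report,
)
from .hapstats import window_h_stats
from .popstats import site_pi, tajimas_d_per_snp, wc_fst_per_snp
from .qc import QcThresholds, filter_panel, ibs_matrix, merge_panels, pca_from_ibs
from .regions import annotate_regions, call_regions, summarize_regions
from .simulate import SimConfig, Sweep, SweepTruth, simulate_scan_dataset

log = logging.getLogger("dcmscan")

SCORE_COLUMNS = [
    "chrom", "pos", "id", "fst", "pi", "tajd", "h1", "h12",
    "p_fst", "p_pi", "p_tajd", "p_h1", "p_h12", "dcms", "p", "q",
]


def child_seed(master: int, name: str) -> int:
    """Deterministic named child seed (< 2^31) from one master seed."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything one scan run needs; see `RunConfig.from_yaml`."""

    vcf: list[str] = field(default_factory=list)
    populations: dict[str, str] = field(default_factory=dict)  # sample -> breed
    gene_models: str | None = None
    gene_models_format: str = "GFF3"
    protein_coding_only: bool = True
    simulate: SimConfig | None = None
    groups: dict[str, str] = field(default_factory=dict)  # breed -> QC group
    thresholds: QcThresholds = field(default_factory=QcThresholds)
    sex_chroms: tuple[str, ...] = ("X", "Y")
    pca_outliers: bool = False
    pca_outlier_z: float = 3.0
    h_window: int = 14
    h_step: int = 1
    smooth_k: int = 31
    tajd_bin: int = 300_000
    alpha: float = 0.75
    nsamp: int = 50_000
    log_base: float | None = None
    sig: float = 0.05
    ext: float = 0.1
    min_seed: int = 2
    include_flank: bool = False
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.get("simulate")
        if sim is not None:
            sim = dict(sim)
            sweeps = [Sweep(**sw) for sw in sim.pop("sweeps", [])]
            d["simulate"] = SimConfig(sweeps=sweeps, **sim)
        if "thresholds" in d:
            d["thresholds"] = QcThresholds(**d["thresholds"])
        vcf = d.get("vcf")
        if isinstance(vcf, str):
            d["vcf"] = [vcf]
        if "sex_chroms" in d:
            d["sex_chroms"] = tuple(d["sex_chroms"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class BreedResult:
    breed: str
    scores: pd.DataFrame         # SCORE_COLUMNS
    corr: np.ndarray
    mu: float
    sd: float
    regions: list
    gene_hits: list


@dataclass
class ScanResult:
    panel: HaplotypePanel
    breeds: dict[str, BreedResult]
    summary: pd.DataFrame
    report: dict
    truth: SweepTruth | None = None


class PipelineError(RuntimeError):
    pass


def _stage(breed: str, stage: str):
    """Context that re-raises any stage error tagged with stage and breed."""
    import contextlib

    @contextlib.contextmanager
    def cm():
        try:
            yield
        except Exception as e:
            raise PipelineError(f"stage {stage!r}, breed {breed!r}: {e}") from e

    return cm()


def load_input_panel(cfg: RunConfig) -> tuple[HaplotypePanel, SweepTruth | None]:
    """Obtain the raw analysis panel from either the simulate block or VCF
    input (multiple VCFs are merged on mutual SNPs)."""
    if cfg.simulate is not None:
        return simulate_scan_dataset(cfg.simulate)
    if not cfg.vcf:
        raise PipelineError("config must provide either 'vcf' or 'simulate'")
    panels = [read_phased_vcf(p, pop_labels=cfg.populations) for p in cfg.vcf]
    panel = panels[0]
    for extra in panels[1:]:
        panel = merge_panels(panel, extra)
    return panel, None


def apply_qc(cfg: RunConfig, panel: HaplotypePanel) -> tuple[HaplotypePanel, dict]:
    """Run QC separately per configured breed group, merge the groups on
    their mutual SNPs (order of the first group), then optionally drop
    IBS-PCA breed-cluster outliers."""
    qc_reports: dict = {}
    if cfg.groups:
        group_of = np.array([cfg.groups.get(b, b) for b in panel.pops])
        merged = None
        for grp in sorted(set(group_of)):
            sub = panel.take_samples(np.flatnonzero(group_of == grp))
            sub, rep = filter_panel(sub, cfg.thresholds, set(cfg.sex_chroms))
            qc_reports[grp] = rep.to_dict()
            merged = sub if merged is None else merge_panels(merged, sub)
        panel = merged
    else:
        panel, rep = filter_panel(panel, cfg.thresholds, set(cfg.sex_chroms))
        qc_reports["all"] = rep.to_dict()

    if cfg.pca_outliers:
        ibs = ibs_matrix(panel)
        _, _, flags = pca_from_ibs(ibs, pops=panel.pops, outlier_z=cfg.pca_outlier_z)
        if flags.any():
            log.info("removing %d PCA outlier sample(s)", int(flags.sum()))
            qc_reports["pca_outliers_removed"] = int(flags.sum())
            panel = panel.take_samples(np.flatnonzero(~flags))
    return panel, qc_reports


def scan_breed(
    panel: HaplotypePanel, breed: str, cfg: RunConfig
) -> BreedResult:
    """Five tracks on the shared panel (FST vs pooled rest; pi, D, H1, H12
    within breed), the composite, its calibration, and region calls."""
    with _stage(breed, "tracks"):
        fst = wc_fst_per_snp(panel, breed, smooth_k=cfg.smooth_k)
        pi = site_pi(panel, breed, smooth_k=cfg.smooth_k)
        tajd = tajimas_d_per_snp(panel, breed, bin_bp=cfg.tajd_bin)
        h1, h12 = window_h_stats(panel, breed, window=cfg.h_window, step=cfg.h_step)
    tracks = [fst, pi, tajd, h1, h12]
    with _stage(breed, "composite"):
        res, P, R = dcms_from_tracks(
            tracks,
            alpha=cfg.alpha,
            nsamp=cfg.nsamp,
            seed=child_seed(cfg.seed, f"mcd:{breed}"),
            log_base=cfg.log_base,
        )
    with _stage(breed, "regions"):
        regions = []
        for chrom, sl in panel.chrom_slices().items():
            regions.extend(
                call_regions(
                    panel.positions[sl], res.q[sl], chrom=chrom, breed=breed,
                    sig=cfg.sig, ext=cfg.ext, min_seed=cfg.min_seed,
                    include_flank=cfg.include_flank, region_offset=len(regions),
                )
            )
    scores = pd.DataFrame(
        {
            "chrom": panel.chroms, "pos": panel.positions,
            "id": panel.variants["id"],
            "fst": fst.values, "pi": pi.values, "tajd": tajd.values,
            "h1": h1.values, "h12": h12.values,
            "p_fst": P.P[:, 0], "p_pi": P.P[:, 1], "p_tajd": P.P[:, 2],
            "p_h1": P.P[:, 3], "p_h12": P.P[:, 4],
            "dcms": res.dcms, "p": res.p, "q": res.q,
        },
        columns=SCORE_COLUMNS,
    )
    return BreedResult(
        breed=breed, scores=scores, corr=R.R, mu=res.mu, sd=res.sd,
        regions=regions, gene_hits=[],
    )


def run_scan(cfg: RunConfig, panel: HaplotypePanel | None = None) -> ScanResult:
    """Run the whole scan for every breed in the panel and (optionally)
    write per-breed tables plus a JSON run-report under ``cfg.outdir``."""
    truth = None
    if panel is None:
        panel, truth = load_input_panel(cfg)
    panel, qc_reports = apply_qc(cfg, panel)
    genes: GeneSet | None = None
    if cfg.gene_models:
        genes = read_gene_models(
            cfg.gene_models, cfg.gene_models_format,
            protein_coding_only=cfg.protein_coding_only,
        )

    breeds = sorted(set(panel.pops))
    results: dict[str, BreedResult] = {}
    all_regions = []
    for breed in breeds:
        log.info("scanning breed %s", breed)
        br = scan_breed(panel, breed, cfg)
        if genes is not None and br.regions:
            with _stage(breed, "annotation"):
                br.gene_hits = annotate_regions(br.regions, genes)
        results[breed] = br
        all_regions.extend(br.regions)

    summary = summarize_regions(all_regions)
    report = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "child_seeds": {f"mcd:{b}": child_seed(cfg.seed, f"mcd:{b}") for b in breeds},
        "qc": qc_reports,
        "n_snps": panel.n_variants,
        "n_samples": panel.n_samples,
        "breeds": {
            b: {
                "mu": r.mu, "sd": r.sd,
                "corr": r.corr.tolist(),
                "n_regions": len(r.regions),
            }
            for b, r in results.items()
        },
    }

    out = ScanResult(panel=panel, breeds=results, summary=summary,
                     report=report, truth=truth)
    if cfg.outdir:
        _write_outputs(out, cfg)
    return out


def _write_outputs(res: ScanResult, cfg: RunConfig) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for breed, br in res.breeds.items():
        br.scores.to_csv(outdir / f"{breed}.scores.tsv", sep="\t", index=False)
        write_region_table(br.regions, br.gene_hits, outdir / f"{breed}.regions.tsv")
    res.summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    write_run_report(res.report, outdir / "run_report.json")
    if res.truth is not None:
        res.truth.records.to_csv(outdir / "sweep_truth.tsv", sep="\t", index=False)
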