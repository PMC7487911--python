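"""Forward-in-time Wright-Fisher simulator with recombination and sweeps.

Generates phased multi-population SNP panels with known selection truth, so
every stage of the scan can be exercised without external data. An ancestral
population is initialized from a neutral-like 1/f allele-frequency spectrum
(sites independent), then evolved for a burn-in period so that drift at
finite N builds linkage disequilibrium appropriate to the population size
and recombination rate. Daughter populations then split and evolve
independently; optionally a focal SNP experiences genic selection
(fitnesses 1 : 1+hs : 1+s) in chosen populations — a hard sweep from
standing variation. There is no recurrent mutation: all variation enters
through the initial frequencies, which is sufficient for sweep footprints
over the short horizons simulated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import HaplotypePanel


@dataclass(frozen=True)
class Sweep:
    """One selective sweep: which population, where, how strong.

    ``initial_freq`` pins the focal SNP's starting frequency in the
    ancestral population (a standing variant); ``None`` leaves it to the
    spectrum draw. ``start_generation`` counts post-split generations before
    selection switches on.
    """

    population: int
    focal_snp: int
    s: float
    h: float = 0.5
    start_generation: int = 0
    initial_freq: float | None = 0.1

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")


@dataclass
class SimConfig:
    """Study-condition parameters of the simulated scan dataset."""

    n_pops: int = 2
    ne: int = 200                       # diploid size of each daughter population
    ancestral_ne: int = 1000            # diploid size of the common ancestor
    split_generations: int = 150
    burn_in_generations: int = 100
    n_snps: int = 3000
    chrom_length_bp: int = 30_000_000
    rec_rate_per_bp: float = 1e-8       # crossovers / bp / gamete / generation
    freq_min: float = 0.05              # initial-SFS truncation (array-like
    freq_max: float = 0.95              # ascertainment of common variants)
    sweeps: list[Sweep] = field(default_factory=list)
    samples_per_pop: int = 25
    seed: int = 0
    chrom: str = "1"
    output_maf: float = 0.0             # optional ascertainment-style filter
    condition_on_survival: bool = False
    max_survival_tries: int = 100

    def __post_init__(self) -> None:
        if min(self.n_pops, self.ne, self.n_snps, self.chrom_length_bp) <= 0:
            raise ValueError("sizes must be positive")
        if self.samples_per_pop > self.ne:
            raise ValueError("cannot sample more diploids than the population holds")
        for sw in self.sweeps:
            if not 0 <= sw.focal_snp < self.n_snps:
                raise ValueError(f"focal SNP index {sw.focal_snp} out of range")
            if not 0 <= sw.population < self.n_pops:
                raise ValueError(f"sweep population {sw.population} out of range")


@dataclass
class SweepTruth:
    """Realized outcome per configured sweep (final population frequency of
    the selected allele; 0 records a lost sweep, not an error)."""

    records: pd.DataFrame

    COLUMNS = ["population", "chrom", "focal_pos", "s", "final_freq"]


def _draw_initial_freqs(
    rng: np.random.Generator, n_snps: int, lo: float, hi: float
) -> np.ndarray:
    """Frequencies from a density proportional to 1/f (the neutral SFS
    shape) truncated to [lo, hi]. The default truncation at MAF 0.05 mimics
    a genotyping array's ascertainment for common variants; widening it to
    [1/(2Ne), 1 - 1/(2Ne)] gives a sequencing-like spectrum instead."""
    u = rng.random(n_snps)
    return lo * (hi / lo) ** u


def _plant_sweep_variant(
    H: np.ndarray, snp: int, freq: float, rng: np.random.Generator
) -> None:
    """Seed a single-origin standing variant at the focal SNP in place.

    One founder haplotype is chosen and copied whole onto round(freq * n_hap)
    rows, all carrying the derived allele; every other row loses it. A hard
    sweep needs the beneficial allele on one haplotype background — drawing
    carriers independently per site would seed a soft sweep with (nearly) no
    haplotype-homozygosity or diversity footprint.
    """
    n_hap = H.shape[0]
    target = max(int(round(freq * n_hap)), 1)
    carriers = np.flatnonzero(H[:, snp] == 1)
    founder = int(rng.choice(carriers)) if carriers.size else int(rng.integers(n_hap))
    founder_hap = H[founder].copy()
    founder_hap[snp] = 1
    H[:, snp] = 0
    others = np.setdiff1d(np.arange(n_hap), founder)
    rows = np.concatenate(([founder], rng.choice(others, size=target - 1, replace=False)))
    H[rows] = founder_hap


def _next_generation(
    H: np.ndarray,
    ne_out: int,
    positions: np.ndarray,
    length_bp: int,
    rec_rate_per_bp: float,
    rng: np.random.Generator,
    focal: int | None = None,
    s: float = 0.0,
    h: float = 0.5,
) -> np.ndarray:
    """One Wright-Fisher generation: fitness-weighted parent choice, one
    recombinant gamete per parent per child."""
    n_par = H.shape[0] // 2
    if focal is not None and s > 0.0:
        geno = H[0::2, focal].astype(np.int64) + H[1::2, focal]
        w = np.choose(geno, [1.0, 1.0 + h * s, 1.0 + s])
        probs = w / w.sum()
    else:
        probs = None
    parents = rng.choice(n_par, size=2 * ne_out, replace=True, p=probs)

    n_gam = 2 * ne_out
    n_cross = rng.poisson(rec_rate_per_bp * length_bp, size=n_gam)
    start_hap = rng.integers(0, 2, size=n_gam)

    # fast path: gametes without crossover copy one parental haplotype whole
    child = H[2 * parents + start_hap].copy()
    for g in np.flatnonzero(n_cross > 0):
        bps = np.sort(rng.integers(1, length_bp + 1, size=n_cross[g]))
        parity = (np.searchsorted(bps, positions, side="right") + start_hap[g]) % 2
        p = parents[g]
        child[g] = np.where(parity == 0, H[2 * p + start_hap[g]], H[2 * p + 1 - start_hap[g]])
    return child


def simulate_scan_dataset(cfg: SimConfig) -> tuple[HaplotypePanel, SweepTruth]:
    """Simulate the configured populations and return a combined phased panel
    of sampled diploids (population labels ``pop0``, ``pop1``, ...) plus the
    realized sweep truth. Fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    positions = np.sort(rng.choice(cfg.chrom_length_bp, size=cfg.n_snps, replace=False)) + 1
    freqs = _draw_initial_freqs(rng, cfg.n_snps, cfg.freq_min, cfg.freq_max)
    for sw in cfg.sweeps:
        if sw.initial_freq is not None:
            freqs[sw.focal_snp] = sw.initial_freq

    anc = (rng.random((2 * cfg.ancestral_ne, cfg.n_snps)) < freqs).astype(np.int8)
    for _ in range(cfg.burn_in_generations):
        anc = _next_generation(
            anc, cfg.ancestral_ne, positions, cfg.chrom_length_bp,
            cfg.rec_rate_per_bp, rng,
        )
    # seed each sweep's standing variant at the split, after burn-in drift,
    # as a single-origin haplotype at its configured frequency
    for sw in cfg.sweeps:
        if sw.initial_freq is not None:
            _plant_sweep_variant(anc, sw.focal_snp, sw.initial_freq, rng)

    sweeps_by_pop: dict[int, Sweep] = {}
    for sw in cfg.sweeps:
        if sw.population in sweeps_by_pop:
            raise ValueError("at most one sweep per population is supported")
        sweeps_by_pop[sw.population] = sw

    hap_blocks: list[np.ndarray] = []
    samples: list[str] = []
    pops: list[str] = []
    truth_rows: list[dict] = []
    for p in range(cfg.n_pops):
        sw = sweeps_by_pop.get(p)
        for attempt in range(cfg.max_survival_tries):
            pop = anc
            for gen in range(cfg.split_generations):
                active = sw is not None and gen >= sw.start_generation
                pop = _next_generation(
                    pop, cfg.ne, positions, cfg.chrom_length_bp,
                    cfg.rec_rate_per_bp, rng,
                    focal=sw.focal_snp if active else None,
                    s=sw.s if active else 0.0,
                    h=sw.h if active else 0.5,
                )
            if sw is None or not cfg.condition_on_survival:
                break
            if pop[:, sw.focal_snp].mean() > 0.0:
                break
        if sw is not None:
            truth_rows.append(
                dict(
                    population=f"pop{p}",
                    chrom=cfg.chrom,
                    focal_pos=int(positions[sw.focal_snp]),
                    s=sw.s,
                    final_freq=float(pop[:, sw.focal_snp].mean()),
                )
            )
        take = rng.choice(cfg.ne, size=cfg.samples_per_pop, replace=False)
        rows = np.ravel(np.column_stack((2 * take, 2 * take + 1)))
        hap_blocks.append(pop[rows])
        samples.extend(f"pop{p}_s{i}" for i in range(cfg.samples_per_pop))
        pops.extend([f"pop{p}"] * cfg.samples_per_pop)

    H = np.vstack(hap_blocks)
    variants = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "pos": positions.astype(int),
            "id": [f"snp{j}" for j in range(cfg.n_snps)],
            "ref": "A",
            "alt": "G",
        }
    )
    panel = HaplotypePanel(variants=variants, samples=samples, pops=pops, H=H)

    if cfg.output_maf > 0.0:
        af = panel.H.mean(axis=0)
        keep = np.minimum(af, 1 - af) >= cfg.output_maf
        panel = panel.take_variants(np.flatnonzero(keep))

    truth = SweepTruth(pd.DataFrame(truth_rows, columns=SweepTruth.COLUMNS))
    return panel, truth


def write_truth_bed(truth: SweepTruth, path) -> None:
    """Sweep truth as BED (0-based half-open single-bp intervals)."""
    with open(path, "w") as fh:
        for r in truth.records.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.focal_pos - 1}\t{r.focal_pos}\t"
                f"{r.population}\t{r.s}\t{r.final_freq}\n"
            )
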