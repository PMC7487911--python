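# Methods

## Overview

`dcmscan` scans phased multi-population SNP panels for signatures of
selection by combining five per-SNP statistics into the de-correlated
composite of multiple signals (DCMS), calibrating the composite to q-values,
and resolving significant runs of SNPs into annotated candidate regions.
This note records the model, the numerical choices, and the places where the
design was genuinely open.

## Quality control

QC runs separately per configured breed group and the groups are then merged
on their mutual SNPs (matching array-analysis practice, where per-group QC
precedes phasing). The cascade is fixed and tallied in order:

1. duplicated variant ids, sex-chromosome and unplaced markers;
2. samples with call rate < 0.95;
3. SNPs with call rate < 0.95;
4. SNPs with minor allele frequency < 0.05 (computed on non-missing alleles);
5. SNPs failing the Hardy–Weinberg 1-df chi-square test at p < 10⁻⁶
   (the plain chi-square, not the exact test).

All thresholds are configurable (`QcThresholds`). The cascade order itself
is a convention — different orders shift counts between tally buckets but
barely change the surviving set — and is reported in the `QcReport` so runs
are auditable. `filter_panel` is idempotent.

Cluster outliers can optionally be removed by an explicit, seedless rule:
samples are placed by PCA of the double-centered identity-by-state matrix
(coordinates = leading eigenvectors × √eigenvalue; double-centering makes
the result invariant to adding a constant to the IBS matrix), and a sample
is flagged when it lies more than `outlier_z` robust standard deviations
(1.4826 × MAD) from its breed's median on PC1 or PC2. The default z = 3 is
deliberately conservative; there is no canonical rule for "outside the
expected breed cluster", so both the rule and the threshold are exposed
rather than hidden.

## The five statistics

All five are computed per SNP on the shared post-QC panel and aligned to
the panel's variant order, so they can be combined SNP-wise.

**F<sub>ST</sub>** — Weir & Cockerham's (1984) single-SNP θ̂ = a/(a+b+c)
for two groups: the focal breed against all remaining samples pooled,
using per-group diploid sample sizes, allele frequencies and observed
heterozygote frequencies. SNPs where either group has fewer than two called
genotypes get 0. Negative estimates are clipped to 0 (they are sampling
noise around zero differentiation), and the track is smoothed per
chromosome with a running median (k = 31, constant end rule).

**π** — per-site nucleotide diversity 2·c₀·c₁/(n(n−1)) from the
population's non-missing chromosomes, smoothed identically to F<sub>ST</sub>.

**Tajima's D** — chromosomes are partitioned into non-overlapping physical
bins (default 300 kb); each bin's D uses the textbook a₁…e₂ constants, the
bin's segregating-site count S and the sum of per-site π, and is assigned
to every SNP in the bin. Bins without segregating sites, or with a
degenerate variance term, get D = 0 (a neutral, non-informative value —
preferable to dropping SNPs, since the composite requires all five
statistics everywhere). The constants use the modal non-missing chromosome
count across the bin's sites; with complete data this is simply 2 × sample
count. The 300-kb default and the missing→0 policy are config-exposed.

**H1 and H12** — for each 14-SNP window (step 1) within a chromosome, the
distinct-haplotype frequency spectrum p₁ ≥ p₂ ≥ … gives H1 = Σpᵢ² and
H12 = (p₁+p₂)² + Σ_{i≥3}pᵢ² = H1 + 2p₁p₂. Haplotypes containing missing
calls are dropped from the window and the spectrum renormalized. H1/H12 and
D are not smoothed (the window and the bin already aggregate).

Two alignment conventions had to be fixed because a window statistic has no
canonical SNP: a window's value is anchored to its ⌈w/2⌉-th SNP (the 7th of
14), and chromosome-end SNPs that receive no window take the nearest
assigned value (constant extension). Both choices exist so that every SNP
carries all five statistics; both are configurable and tested.

## The composite

Each track is converted to one-tailed p-values by genome-wide fractional
rank: with ascending mean-tie ranks r over N SNPs, left-tail p = r/(N+1)
and right-tail p = (N+1−r)/(N+1). Left tails are used for π and D (low
values are sweep-like), right tails for F<sub>ST</sub>, H1, H12. The N+1
denominator keeps every p strictly inside (0, 1), which the logit transform
requires; being rank-based, the p-values are invariant to any strictly
monotone transform of a raw track.

The n × n correlation among the five raw (smoothed) tracks is estimated
robustly by FAST-MCD with α = 0.75: h = ⌈αN⌉; each of `nsamp` random
(n+1)-point elemental subsets is concentrated by C-steps (recompute
location/scatter from the h points with smallest Mahalanobis distance) until
its support stabilizes; the minimum-determinant solution is Fisher-
consistency corrected and reweighted with the χ²(n) 0.975 cutoff; the
scatter is converted to a correlation matrix. When all (n+1)-subsets number
no more than `nsamp` they are enumerated exhaustively, which makes the tiny-
sample behaviour checkable against a brute-force oracle. Exactly duplicated
columns (which make every scatter singular) are deduplicated and re-entered
with r = 1. Concentrated subsets that end singular ("exact fit": ≥ h points
on a hyperplane) cannot yield a correlation and are skipped; if every subset
is singular the input is reported as degenerate. A seed is a required
argument; the default `nsamp` is 50,000 for full runs, and the pipeline's
tests use 500.

The composite at SNP l is DCMS_l = Σ_t logit(1−p_lt)/w_t with
w_t = Σ_i |r_it|. The natural logarithm is used — the log base only rescales
the scores, and the scale cancels in the normal calibration that follows —
and is config-exposed. By construction 1/n ≤ 1/w_t ≤ 1; this bound is
asserted every time a correlation matrix is built.

Calibration fits an intercept-only Huber M-estimate to the DCMS vector:
initialization at the median with scale 1.4826 × MAD; iterated Huber
weights w = min(1, k/|u|), k = 1.345, with the scale re-estimated from the
MAD of residuals each iteration; convergence when the location moves by
less than 10⁻⁸ × scale. This mirrors a robust linear model `x ~ 1` with
default Huber tuning. Upper-tail normal p-values under the fitted N(μ, σ)
are then adjusted by Benjamini–Hochberg (step-up, via statsmodels).

## Region calling and annotation

A run of at least `min_seed` (default 2 — "consecutive" read as plural)
SNPs with q < 0.05 seeds a region; it extends outward over flanking SNPs
with q ≤ 0.1 and stops just before the first flanking SNP above 0.1 (the
boundary is the last included SNP's position; the inclusive alternative is
selectable). Extensions that touch or overlap merge, keeping the overall
minimum-q SNP as the peak. Genes overlapping a region are ranked by distance
from the peak SNP to the nearest gene edge (0 if the peak lies inside the
gene), ties broken by genomic start — rank 1 is the closest gene. Summaries
report, per breed, region counts, mean ± SD length in kb, significant-SNP
counts and total length in Mb.

## The simulator

`dcmscan.simulate` is a forward Wright–Fisher simulator whose job is to
produce phased multi-population panels with the statistical structure the
scan assumes: populations diverged from a common ancestor, biallelic SNPs
with LD from drift and recombination, and optional hard sweeps with known
truth.

A diploid ancestral population (`ancestral_ne`, default 1000) is
initialized from a 1/f allele-frequency law truncated to [0.05, 0.95] —
the 1/f shape is the neutral SFS, and the truncation mimics a genotyping
array's ascertainment for common variants, which is the kind of data the
scan targets; widening the truncation to [1/(2Ne), 1−1/(2Ne)] recovers a
sequencing-like spectrum. Sites start in linkage equilibrium and a burn-in
(default 100 generations) lets drift build LD. Daughter populations
(default 2 × Ne = 200) then split and evolve independently for
`split_generations` (default 150): each offspring draws two parents
(fitness-weighted 1 : 1+hs : 1+s at the focal genotype in swept
populations) and receives one recombinant gamete per parent, with Poisson
crossover counts (rate = `rec_rate_per_bp` × length; default 10⁻⁸/bp, about
1 cM/Mb) and uniform breakpoint positions. There is no recurrent mutation:
variation enters only through the initial frequencies, which suffices for
sweep footprints over these short horizons. Finally `samples_per_pop`
diploids (default 25, typical of livestock diversity panels) are drawn
without replacement per population.

A configured sweep is seeded at the split as a **single-origin standing
variant**: one founder haplotype is replicated so the focal allele sits at
`initial_freq` (default 0.1) on a single background. This matters: drawing
carriers independently per site would distribute the allele across dozens of
backgrounds and produce a soft sweep with essentially no haplotype-
homozygosity or diversity footprint. Sweep loss is recorded in the truth
table (final frequency 0), not raised; conditioning on survival is off by
default so neutral-behaviour tests are unbiased. Everything is reproducible
from one seed.

What the generator does **not** emulate: recurrent and back mutation,
variable recombination maps, genotyping error, ascertainment bias beyond the
initial MAF truncation, overlapping generations, migration after the split,
and real pedigree structure. Passing tests on simulated data therefore show
that the pipeline detects drift-versus-sweep contrasts of realistic
magnitude — not that it is robust to every artefact of real array data.

## Problem sizes, seeds and runtime

The test suite runs the full pipeline at the scale of a single 30-Mb
chromosome with 3000 array-like SNPs and two populations of Ne = 200
(25 sampled diploids each) — about 2 s to simulate and 2 s to scan per
replicate — with 20 sweep replicates and 10 neutral replicates in the
end-to-end tests, and `nsamp` = 500 for the MCD inside the scan. One master
seed fans out to named child seeds (one per breed for the MCD, one for the
simulator) so stages are independently reproducible.

## Known limitations

- **Desk-scale calibration.** On a 30-Mb genome the composite reliably
  *ranks* a completed hard sweep at the top (in our end-to-end runs the
  swept population's DCMS argmax falls within 2 Mb of the true focal SNP in
  the large majority of replicates), but the q < 0.05 certification is
  borderline: the sweep footprint (1–3 Mb) is several percent of all SNPs,
  so its own tie cluster floors the fractional-rank p-values, and the ~60
  independent drift blocks of such a genome widen the DCMS null that the
  Huber-normal fit estimates. On genome-wide data (10⁵ SNPs across tens of
  chromosomes) both effects shrink by two orders of magnitude. The
  recovery-rate test in `tests/test_acceptance.py` documents this honestly
  rather than relaxing the threshold.
- With exactly two populations the F<sub>ST</sub> contrast "focal vs rest"
  is the same track for both populations, so a sweep in one population
  contributes differentiation signal to the other's scan (the other four
  statistics keep the scans apart).
- The HWE filter uses the chi-square approximation, which is anticonservative
  for rare alleles; with the MAF ≥ 0.05 filter in the same cascade this is
  immaterial.
- Tajima's D within short bins on array data is noisy and its missing→0
  policy shrinks its contribution toward neutrality in empty bins.
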