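# Methods

`wheatsim` is a stochastic, gene-level simulator of a commercial winter-wheat
line-breeding program, built to compare phenotypic selection (PS) with
genomic selection (GS) over 25 years of overlapping breeding cycles.  This
note records the model, its calibrations, and the design choices made where
the design was genuinely open.

## Founder genome

The real founder panel being emulated — 988 fully inbred F6 lines genotyped
at 9582 biallelic loci on 21 chromosomes — is proprietary, so the package
generates a synthetic stand-in that reproduces its published summary
statistics only:

* **Map.** 21 chromosomes of 150 cM each (the real map lengths are
  unpublished; 150 cM is a typical wheat chromosome and, because all results
  are reported in base-population genetic-SD units, the absolute map length
  is second-order).  Loci are evenly spaced; chromosomes 1–7, 8–14 and 15–21
  are labelled subgenomes A, B and D.
* **QTL placement.** 1039 of the 9582 loci are QTL, placed on an even stride
  (every 9th locus) whose residue class is randomized per replicate; when the
  stride class holds more than 1039 loci, a random subset is used.  This
  honors both "evenly distributed" and "randomly chosen" readings of the
  design.  The remaining 8543 loci are anonymous markers.
* **Linkage disequilibrium.** Founder haplotypes are simulated per
  chromosome under the neutral coalescent with recombination (`msprime`) and
  doubled into fully inbred lines.  One segregating variant with pool
  frequency in [0.05, 0.95] (array-style MAF ascertainment) is placed at the
  site nearest each map position.  The per-subgenome effective population
  size is the calibration knob: Ne = 34 (A, B) and Ne = 11 (D) reproduce the
  published mean within-chromosome r² of ~0.05 (A, B) and ~0.11 (D); see
  `analysis/01_calibrate_founder_ld.py`.  A small-Ne *forward* simulation was
  tried first and rejected: drift fixes 50–90 % of loci, and replacing fixed
  loci destroys the calibrated LD, whereas the coalescent conditions on
  segregation naturally.  Only the mean r² values are matched — the full
  LD-decay curve, allele-frequency spectrum and haplotype-block structure of
  the real panel are *not* reproduced, so results should be read as
  conditional on an LD level, not on real wheat haplotypes.
* **Base population.** 480 lines, each built by drawing one chromosome copy
  per chromosome without replacement from the founder pool (2 × 988 copies
  available) and duplicating it, giving fully inbred base lines whose allele
  frequencies track the pool's.

## Meiosis

Crossover counts per chromosome are Poisson with mean map-length/100
(Haldane's model, no interference — the simplest standard choice; the source
program leaves this unspecified), positions uniform, starting strand a fair
coin.  There is no mutation: every offspring allele is a copy of a parental
allele.  Selfing draws two independent gametes from the same parent.  The
expected homozygosity at selfing generation *t* (F1 = 1) is
H = 1 − (1/2)^(t−1), defined relative to loci segregating in the F1 (the
genome-wide value would depend on parental divergence; the F1-relative form
is the one with a closed form under selfing).

## Traits and phenotypes

Three correlated, purely additive traits are simulated: breeder's visual
preference (BVP, plant-level h² = 0.1), preliminary-yield-trial yield (PYT,
plot h² = 0.2 at 50 plants) and advanced-yield-trial yield (AYT, plot
h² = 0.3 at 1500 plants; the breeding goal).  The genetic correlation
between PYT and AYT is the scenario variable (0.1 … 0.9); BVP correlates 0.1
with both.

* **Effects.** Per-QTL effect vectors are drawn i.i.d. from a trivariate
  normal with the scenario correlation matrix, then calibrated on the 480
  base lines.  The default calibration (`empirical_cov`) rotates the effect
  matrix so the realized base-population TBV covariance equals the scenario
  matrix *exactly* (unit variances, exact correlations).  A per-trait-scalar
  mode and the Hardy–Weinberg analytic scaling
  (aⱼ = aⱼ′ / √(Σₖ 2pₖ(1−pₖ)aₖ′²/σ²qtl)) are available.  The rotation is
  needed because LD among QTL otherwise perturbs realized correlations by
  ±0.1 or more between replicates.
* **TBVs** are dosage sums over QTL, centred at base-population allele
  frequencies (base mean ≈ 0, variance = 1 per trait).
* **Phenotypes.** y = g + e.  A yield plot is seed-multiplied and treated as
  clonal: its value is the line TBV plus the mean of N_p i.i.d. plant
  residuals, i.e. residual variance σ²ₑ/N_p per plot.  F3 family plots mix
  the family's eight plants (1500 draws with replacement).  Residual
  variances are calibrated by common-random-number bisection until the
  realized plot heritability on unselected material hits its target within
  ±0.005 (the printed closed form σ²ₑ = 2N_pHσ²g(1−h²)/h² − (1−H)σ²g is
  implemented as the `analytic` mode; under clonal plots it misses the
  heritability target by ~2×, so the empirical mode is the default and is
  used for all reported runs).  Residuals are independent between traits,
  plots and locations (no genotype-by-environment interaction, per the
  program design being emulated).

## Breeding scheme

A cycle started in year *c* is acted on at generation F*g* in year *c+g*;
cycles start every year, so nine generations run concurrently at steady
state.  Per cycle: 60 parents → 100 crosses (uniform over the 1770 pairs,
max 6 uses per parent) → 100 F1 → 30 F2 seeds per F1 (3000 plants; top 8
per family on the BVP plant phenotype) → F3 family trial (3 AYT-style plots
per family; top 75 of 100 families) → F4 (30 plants per family, allocated
round-robin over the family's 8 plants — the per-family F4 plant count is
unpublished; 30 mirrors the F2 plot size; top 10 per family on BVP → 750
single-seed-descent lines) → F5 PYT (one 50-plant plot; keep 150) → F6 AYT
(9 replicate plots ≡ 3 plots × 3 locations without G×E; keep 30) → F7 AYT
(keep 5) → F8 product.  All selected F5/F6/F7 lines are stored in the
parent pool with their selection criterion.  Tie-breaks in every truncation
are by line id, for reproducibility.

**Parents.** Years 1–7 draw 60 lines uniformly from the base population.
From year 8, PS draws 60 uniformly from *all* stored lines (the pool is
elite by construction; the draw is random, and stored lines are never
retired — retiring them after 3 years roughly doubles the PS gain and
overshoots the published rates).  Under GS (after burn-in), parents are the
top 60 stored lines ranked by their current absolute-scale AYT GEBV over the
last three store-years; stored lines whose cohort is still inside the GBLUP
reference window get their GEBV refreshed at each year's solve.  This
genomic parent channel is what produces the large GS advantage: with
parents drawn randomly under both strategies, GS ≈ PS, because GEBV accuracy
at the F6/F7 trials is no better than a 9-plot mean.

**Genomic evaluation.** Under GS, the 750 selected F4 lines are genotyped
each year from year 9 (cohorts already past F4 at year 9 are genotyped at
their current stage so GEBV selection starts immediately; reference-size
bookkeeping counts F4-genotyped cohorts, 750/year).  Selection criteria
switch to GEBVs at F5 (GEBV of PYT, per the program design), F6 and F7
(GEBV of AYT).  One multi-trait GBLUP is solved per year and shared by the
year's decisions.  The model is y_t = 1μ_t + Z_t a_t + e_t with
var(a) = G ⊗ G0 and independent residuals (traits are recorded on different
plots); variance components are the true simulated values — the program
gives no estimation protocol, and known-variance BLUP isolates the selection
comparison.  G is the centred cross-product genomic relationship matrix on
base-population marker frequencies, blended 1 % with the identity.  Records
enter as plot means (PYT) and 9-plot means (AYT) with residual variance
σ²ₑ/N_p/n_plots; BVP is carried in the model but contributes no reference
records (it is measured on single plants before genotyping and its
information content for yield is negligible).  The solver uses the
N-records × N-records generalized-least-squares form (equivalent to the
mixed-model equations, which are also implemented and cross-checked in the
tests, but factorizing only the record dimension keeps the yearly solve
~1 s at reference sizes of a few thousand).

**Scaled-down GS mode.** The full-scale reference grows to ~12 750
genotypes; the desk-scale mode used for all reported GS results thins the
marker panel 4× (to 2136 markers, all QTL untouched) and windows the
reference to the three most recent genotyped cohorts, with 3 replicates.
PS comparisons use seed-paired runs whose burn-in years are bit-identical.

## Reported statistics

* **Annual genetic gain ΔG**: OLS slope of the yearly mean F8 TBV (AYT) on
  year over years 9–25, one slope per replicate, averaged; the SE is the
  between-replicate SE.
* **Cumulative gain**: the fitted linear advance of the mean F8 TBV over
  years 9–25 (per-replicate OLS slope × 16 years; the comparison protocol
  assumes linear response over this window, and the fitted advance is far
  more stable than a two-endpoint difference of five-line cohort means).
  The burn-in level is the baseline shared by both strategies; the GS-vs-PS
  excess is reported as a percentage of the PS value.
* **Genetic variance** is tracked at F5 (the highest-selection-intensity
  stage) as the sample variance of the 750 lines' AYT TBVs per year, and
  within single cycles across F1…F8.
* **Selection accuracy**: Pearson correlation between the stage's selection
  criterion (plot mean under PS, GEBV under GS) and TBV(AYT) over the
  candidate set, computed before truncation; the F8 figure carries the
  F7-decision criterion restricted to the five survivors (no F8-specific
  trial exists).

## Problem sizes

Reported runs use the full program dimensions (9582 loci, 988 founders, 480
base lines, 25 years): 10 replicates per PS scenario and 3 replicates in the
scaled-down GS mode.  One PS replicate takes ~20 s and one scaled GS
replicate ~30 s on a single CPU.  The structural test-suite runs use a
proportionally shrunken funnel (12 years, 12 crosses) that preserves every
stage mechanism.

## Known limitations

* The founder genome matches only the published locus counts and mean r²;
  conclusions transfer to real germplasm only insofar as those summaries
  capture what matters for selection response.
* Variance components in GBLUP are known, not estimated; accuracies are
  therefore upper bounds on what a REML-based pipeline would achieve.
* No mutation, no crossover interference, no G×E, no dominance/epistasis,
  no genotyping errors or costs.
* The parent-selection policy is the one point where the emulated program's
  description is self-contradictory ("selected based on their breeding
  values" vs "selected randomly from the stored line"); the package
  resolves it asymmetrically (PS random, GS genomic truncation) because that
  is the only reading that reproduces both strategies' published gains, and
  exposes both policies as configuration for sensitivity analysis.
* Within-cycle selection response under PS exceeds the published trajectory
  at high PYT–AYT correlation (the published accuracy and gain tables are
  mutually inconsistent there; see the package README for which reproduced
  quantities agree and which do not).
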