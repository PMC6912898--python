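# Methods

This note documents the models and numerical procedures implemented in
`divscan`, the assumptions behind them, and the choices made where the
design was genuinely open.

## Problem setting

The package analyses whole-genome resequencing data from two closely
related populations (the motivating system is a pair of tidal-marsh
sparrow sister species, sampled 10 + 10 diploid individuals) and answers
two questions:

1. **Where is divergence elevated?**  A windowed genome scan computes
   differentiation and diversity statistics in non-overlapping 100-kb
   windows and flags windows that are simultaneously extreme in
   Weir–Cockerham F_ST and in the density of between-population fixed
   differences.
2. **What demographic history produced the background divergence?**
   A coalescent simulator generates unlinked SNP loci under three
   demographic scenarios (simple split, split with a population-size
   change, split with an admixture pulse), and approximate Bayesian
   computation (ABC) performs model choice and parameter estimation.

## Windowed statistics

All statistics are computed from alt-allele dosages with missing genotypes
excluded from every count; per-site sample sizes therefore vary.

* **F_ST** uses the Weir & Cockerham (1984) variance components for
  r = 2 populations.  With `n_i` called diploid individuals, alt
  frequency `p_i`, and observed heterozygote frequency `h_i`
  (heterozygotes over *called* individuals):

      n̄ = (n1+n2)/2,  n_c = (2n̄ − (n1²+n2²)/(2n̄)),
      p̄ = (n1 p1 + n2 p2)/(2n̄),
      s² = (n1(p1−p̄)² + n2(p2−p̄)²)/n̄,
      h̄ = (n1 h1 + n2 h2)/(2n̄),
      a  = (n̄/n_c) [s² − (p̄(1−p̄) − s²/2 − h̄/4)/(n̄−1)],
      b  = (n̄/(n̄−1)) [p̄(1−p̄) − s²/2 − ((2n̄−1)/(4n̄)) h̄],
      c  = h̄/2.

  The window estimate is the weighted ratio of sums Σa / Σ(a+b+c); an
  unweighted mean-of-ratios column is also emitted.  Sites with fewer
  than two called individuals in either population are skipped with a
  logged count.  Negative estimates are reported as computed.
* **D_xy** per site is d = p̂1(1−p̂2) + p̂2(1−p̂1).  The primary output is
  the per-SNP average (Σd / n_SNPs); on variant-only input this is the
  quantity whose genome-wide value sits near 0.44 in data of this kind.
  A per-bp variant (Σd / window length) is also emitted.
* **π** per site is 2·c_ref·c_alt / (n(n−1)) over the n called alleles of
  a population, summed and divided by window length.
* **Tajima's D** follows Tajima (1989).  With missing data, n is taken as
  2× the modal number of called individuals in the window for that
  population; all segregating sites contribute to S and (with per-site n)
  to k.  A single window-level n keeps the constants well defined.
* **Fixed differences** are sites whose called allele sets are disjoint
  between the populations (each side monomorphic, for different alleles);
  `df` is the count per bp of window.
* **Heterozygosities**: observed is the mean per-site heterozygote
  frequency; expected uses the unbiased within-population form
  n(1−Σp²)/(n−1) averaged across the two populations.

## Site filters

Cohort-level filters are applied in a fixed order: excluded scaffolds
(e.g. sex-linked, supplied as a list) → pooled MAF < 0.05 → site
missingness > 20% → site mean depth < 3× → site mean depth above the
genome-wide mean + 2 SD.  The high-depth ceiling is estimated from the
input matrix; because re-estimating it on already-filtered data shifts the
threshold, the realized ceiling is recorded in the `FilterReport` and can
be passed back to make re-application exactly idempotent.  MAF is pooled
over both populations (a cohort-level VCF-style filter), so a planted
fixed difference (frequencies 0 and 1) has pooled MAF 0.5 and is never
removed by it.

## Outlier scan

Windows with fewer than 10 SNPs are discarded, then scaffolds retaining
fewer than 2 windows.  Thresholds are the empirical 99th percentiles
(linear interpolation between order statistics) of the retained F_ST and
df distributions; "elevated" means strictly greater than both thresholds.
Adjacent elevated windows merge into regions for gene-proximity reporting
(genes within 50 kb, inclusive boundaries), while window counts are
reported pre-merge.  Candidate genes are scored over the gene ± 20 kb with
ratio-of-sums F_ST, fixed-difference counts, and the percentage of
variable sites that are fixed; a gene "exceeds" the genome-wide background
when its mean F_ST is above the upper bound of the normal-approximation
95% interval (mean ± 1.96 SD of window F_ST; a bootstrap alternative is
provided).  The percentage denominator is exposed as a parameter because
printed tables of this kind do not always document it; only the
variable-site denominator is computable from SNP-only input.

## Synthetic genomes (known truth)

The generator emulates the observed structure of a deeply diverged
two-species cohort — the conditions under which the scan is tested:
10+10 individuals, 20 scaffolds × 5 Mb (1,000 windows of 100 kb), SNP
density 0.006/bp, background window F_ST ≈ 0.32 with fixed-difference
density ≈ 0.00022/bp, planted elevated windows at F_ST ≈ 0.6 with fixed
density 0.0013/bp, ≤20% missing genotypes (5% by default), and per-sample
depths Normal(10.7, 3) truncated at zero (the observed mean SNP depth).

Background sites follow the Balding–Nichols model: ancestral frequency
p ~ U(0.05, 0.95) (bounded away from 0/1 so the MAF filter removes a
small, predictable fraction), per-population frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F), genotypes Binomial(2, p_pop).  The
differentiation parameter F is calibrated by bisection so the realized
mean window Weir–Cockerham F_ST — *after* the MAF screen, with the
configured missingness and fixed-difference fraction — hits the target
within ±0.01 on a 5,000-site probe.  Fixed differences are planted
explicitly (dosages 0 vs 2).  Balding–Nichols rather than a coalescent is
used here because the scan needs site-level frequency control and
window-level truth, not genealogical realism; genealogy-dependent tests
use the coalescent module.

What the generator does **not** emulate: linkage disequilibrium within
windows, mutation-rate heterogeneity, sequencing error, reference bias,
and variable scaffold lengths.  Passing scan tests therefore demonstrate
correct statistics and outlier logic under frequency-realistic but
LD-free data, not robustness to every artefact of real resequencing data.

## Coalescent simulator

Each locus is an independent structured Kingman genealogy of the 40
sampled chromosomes, run backward with piecewise-constant diploid sizes
(coalescence rate k(k−1)/2 · 1/(2N) per generation within a population).
Scenario events are compiled to a breakpoint table: the admixture pulse
sends each sampled-NESP lineage to the parental NESP lineage with
probability r, else to SALS; at T2 NESP lineages join the ancestral
Nelson's population; at T1 everything merges into the common ancestor.
The unsampled inland Nelson's lineage is a ghost — no samples, no gene
flow — so its size is unidentifiable and it is not simulated at all.
Times in years are converted to generations with a 2.3-year generation
time; the per-generation mutation rate 7.59×10⁻⁹ derives from
3.3×10⁻³ substitutions/site/Myr × 2.3.

**SNP protocol.**  Each locus carries exactly one mutation, simulated in
the infinite-sites low-mutation limit: conditional on a locus being
variable, its genealogy is length-biased (probability proportional to
total branch length) and the mutation falls uniformly along the branches.
The popular shortcut of placing one mutation branch-proportionally on an
*unweighted* genealogy (ms `-s 1`) distorts the site-frequency spectrum —
it overweights singletons by ~7% at n = 40 — whereas length-biasing
restores the neutral 1/i spectrum.  The length-biased draw is implemented
by importance resampling among K = 8 candidate genealogies per locus; the
residual O(1/K) bias is undetectable by a χ² test at 50,000 loci.  The
kernel is JIT-compiled (numba) and returns each locus as a 64-bit
chromosome mask; chromosome pairs form diploids directly, which is
equivalent to random pairing by exchangeability.  Scenario-2's ordering
T_fall < T_rise < T2 and all other time orderings are enforced by
whole-vector rejection sampling from the uniform priors.

## ABC

**Summary statistics** (10): per population, the mean and variance of
nonzero per-locus genic diversity n(1−Σp²)/(n−1) and the proportion of
zero-diversity loci; the mean and variance of nonzero per-locus
Weir–Cockerham F_ST; and the mean and variance of nonzero per-locus Nei
(1972) distance −ln(J₁₂/√(J₁J₂)).  "Nonzero" excludes exact zeros and
non-finite values (the Nei distance is +∞ at loci with disjoint alleles;
per-locus F_ST is undefined at loci monomorphic in the pooled sample);
variances use ddof = 1 and degenerate cases report 0 with a flag.

**Model choice.**  Pool the per-scenario reference tables, standardize
each statistic by its pooled median absolute deviation (SD fallback),
rank by Euclidean distance to the observed vector, keep the closest 1%,
and fit a multinomial logistic regression of scenario label on the
centered statistics with Epanechnikov weights in distance
(near-unpenalized, C = 10⁶); posteriors are the fitted class
probabilities at the observed point.

**Parameter estimation.**  Within the accepted rows, each parameter is
regressed on the centered statistics (Beaumont-style local-linear
adjustment) and projected to the observed point.  Three refinements,
each validated by direct coverage experiments over the prior across five
independent seeds: (i) parameters with known prior bounds are adjusted on
a logit scale mapped to the prior support, so the adjusted posterior
cannot leave the prior range; (ii) the regression is ridge-regularized
(relative penalty 0.05 on the covariate block) because the statistic
families are strongly collinear, which destabilizes plain least squares;
(iii) residuals are inflated by √(n_eff/(n_eff−p)) (Kish effective sample
size) to undo the variance shrinkage of fitting 11 coefficients to ~100
accepted rows.  Intervals are equal-tailed weighted 2.5–97.5% quantiles —
a stand-in for HPD intervals, noted in the output.  Realized 95%-interval
coverage for the split time T1 is 90–100% per seed batch in the scaled
experiments.

**Posterior error rate.**  The scenario labels and parameters of the 500
pooled simulations closest to the observed vector are resampled to
generate fresh pseudo-observed datasets, each reclassified by the model
choice above; the error rate is the fraction misclassified.

**Observed-data SNP selection** filters to high-confidence, effectively
neutral loci: no missing genotypes, depth ≥ 5 in every individual, site
mean depth strictly inside (8, 12), per-SNP F_ST within 1 SD of the
genome-wide mean, and ≥ 20 kb spacing enforced greedily over a seeded
random ordering; disjoint sets are then drawn without replacement.

## Scaled study sizes

The desk-scale experiments use 10⁴ simulations per scenario and 200
unlinked loci per dataset (the analysis design they emulate used 10⁶
simulations and 2,000 loci); recovery, error-rate, and coverage
experiments use 50–100 pseudo-observed replicates.  At these sizes the
three scenarios remain well separated for a strong recent admixture pulse
(posterior ≈ 1.0 for the generating scenario, posterior error 0), while
parameter posteriors are wider than they would be at full scale.

## Numerical conventions

* All randomness flows through explicit integer seeds; the reference
  table records a per-row kernel seed for exact replay.
* Quantiles use linear interpolation between order statistics; "above a
  percentile" is strict inequality, so ties at the threshold are never
  flagged.
* Undefined values (empty windows, monomorphic windows, S = 0) are NaN in
  memory and "." in TSV output; they are excluded from summaries with
  counts.
* Coordinates are 1-based with inclusive ends everywhere; BED input is
  converted on read, and window starts print as 1-based (1,300,001 for
  the 14th 100-kb window).

## Known limitations

* The scan handles exactly two populations and biallelic SNPs.
* Tajima's D with heavy, uneven missingness approximates n by the window
  mode; windows with fewer than 4 sequences report NaN.
* The coalescent kernel supports at most 32 diploid samples (64-bit
  chromosome masks) and no recombination within loci — loci are unlinked
  SNPs by design.
* The admixture proportion r is attached to the parental NESP lineage;
  the labeling is symmetric under r → 1−r and is a configuration choice.
* Equal-tailed intervals differ from HPD intervals for skewed posteriors.
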