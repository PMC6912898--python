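# divscan

Windowed divergence scans and coalescent demographic inference for
two-population whole-genome resequencing data.

`divscan` is built for the classic comparative-genomics design in which
two recently diverged populations or sister species (the motivating
system is a pair of tidal-marsh sparrows, 10 + 10 resequenced diploid
individuals) are compared genome-wide to separate the signatures of
divergent selection from those of demographic history.  It provides:

* **Variant handling** — biallelic-SNP VCF input, cohort filters (pooled
  MAF ≥ 5%, ≤ 20% missingness, mean-depth screens, scaffold exclusion),
  and non-overlapping 100-kb window tiling.
* **Window statistics** — Weir–Cockerham F_ST (weighted ratio of sums of
  the a, b, c variance components), absolute divergence D_xy, nucleotide
  diversity π, Tajima's D, observed/expected heterozygosity, and the
  density of between-population fixed differences (df), all implemented
  from first principles and cross-checked against independent
  transcriptions of the published estimators.
* **Outlier scan** — dual 99th-percentile outlier detection (windows
  strictly above the empirical thresholds of *both* the F_ST and df
  distributions), merging of adjacent elevated windows into regions, gene
  models within 50 kb of each region, and candidate-gene scoring over
  gene ± 20 kb against the genome-wide 95% confidence interval.
* **Demographic ABC** — a JIT-compiled structured-coalescent simulator
  for three scenarios (simple split; split with a population-size change;
  split with an admixture pulse into the sampled Nelson's lineage), DIYABC-style
  unlinked SNP loci, ten summary statistics (genic diversity, pairwise
  F_ST, Nei distance families), logistic-regression model choice on the
  closest 1% of simulations, ridge-regularized local-linear parameter
  posteriors, and posterior predictive error rates.
* **Synthetic data with known truth** — calibrated Balding–Nichols
  genomes with planted elevated windows, planted candidate genes,
  missingness and depth structure, so every pipeline stage is testable
  without any external download.

The scan and the ABC stage are exposed as model objects in the
statsmodels idiom: build a model from data, call `fit()`, and read
estimates, intervals, and a `summary()` from the results object.

## Core model

For two populations with `n_i` called diploid individuals, alt-allele
frequency `p_i`, and observed heterozygote frequency `h_i` at a site, the
Weir–Cockerham components are

    a = (n̄/n_c)[s² − (p̄q̄ − s²/2 − h̄/4)/(n̄−1)]
    b = (n̄/(n̄−1))[p̄q̄ − s²/2 − ((2n̄−1)/4n̄)h̄]
    c = h̄/2

and a window's F_ST is Σa / Σ(a+b+c).  A window is *elevated* when both
its F_ST and its fixed-difference density df = n_fixed/L lie strictly
above the 99th percentiles of their genome-wide empirical distributions.
Demographic scenarios are priors over split times (T2 < T1), effective
sizes, and an admixture pulse (time T_admix < T2, proportion r), with
years converted to generations at 2.3 yr/generation and the mutation
rate 3.3×10⁻³ subs/site/Myr × 2.3 = 7.59×10⁻⁹ subs/site/generation.

## Worked example

Generate a synthetic 200-window genome with two planted divergence
islands, filter it, and scan it:

```python
from divscan import (SyntheticGenomeConfig, PlantedWindow, generate_genome,
                     SiteFilterConfig, apply_site_filters, DivergenceScan)

cfg = SyntheticGenomeConfig(
    n_scaffolds=10, scaffold_length=2_000_000,
    planted_windows=[PlantedWindow("scaffold_2", 5), PlantedWindow("scaffold_7", 11)],
    seed=7)
gm, truth, genes = generate_genome(cfg)
gm, report = apply_site_filters(gm, SiteFilterConfig())
results = DivergenceScan.from_genotypes(gm).fit()
print(results.summary())
```

```
Divergence scan summary
=======================================================
retained windows            200
F_ST threshold (q=0.99)    0.367829
df threshold (q=0.99)      0.0003685
flagged by F_ST             2
flagged by df               2
intersection windows        2
intersection scaffolds      2
merged regions              2
genome-wide F_ST 95% CI     (0.2601, 0.3937)

Inside vs outside elevated windows (mean (SD)):
  fst          inside 0.6123 (0.0259)   outside 0.32403 (0.0183)
  dxy_per_snp  inside 0.57916 (0.00858)   outside 0.44683 (0.00798)
  df           inside 0.00123 (2.83e-05)   outside 0.00022702 (4.73e-05)
  pi_pop1      inside 0.001079 (0.00021)   outside 0.001533 (7.83e-05)
  ...
```

The two planted windows are exactly the two intersection windows: the
background realizes the calibrated mean window F_ST of 0.32, the planted
windows sit near their 0.6 target with a fixed-SNP density of ~0.0013/bp
against a ~0.00022/bp background, and diversity (π) is lower inside the
elevated windows than outside — the pattern a selection scan is built to
detect.  `results.elevated_windows`, `results.regions`,
`results.genes_near_regions(genes)` and
`results.candidate_gene_reports(genes)` expose the tables behind the
summary.

For demographic inference, build per-scenario reference tables and fit:

```python
from divscan import (Scenario, build_reference_table, DemographicABC,
                     compute_summary_stats)

tables = {sc: build_reference_table(sc, n_sims=10_000, n_loci=200, seed=i)
          for i, sc in enumerate(Scenario)}
abc = DemographicABC(compute_summary_stats(snp_gm), tables)
fit = abc.fit()
print(fit.summary())        # scenario posteriors + parameter intervals
fit.error_rate(n_pseudo=100, seed=0)
```

On data simulated under a strong recent admixture pulse the admixture
scenario receives posterior probability 1.0000 and a posterior
predictive error rate of 0.00 at this desk scale.

A `divscan` command-line interface wraps the same stages
(`divscan synth genome`, `divscan scan run`, `divscan abc
simulate|choose|estimate|error-rate|select-snps`); every run writes a
JSON manifest with the config hash and per-stage counts.

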