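# Methods

`rarecollapse` implements a gene-level rare-variant association analysis
for a case–control exome cohort, in three passes: a primary carrier-
collapsing scan of rare inactivating variants (RIVs), a secondary scan of
rare damaging variants (RDVs), and a tertiary sequence kernel association
test (SKAT) over the non-synonymous tier.  A synthetic cohort generator
supplies test data with the same statistical structure, including
scenarios that replant the published carrier counts of the motivating
colorectal-cancer study (146 cases, 1395 controls) so that every printed
association statistic can be regenerated end to end.

## Variant tiers

Annotated alternate alleles are assigned to nested tiers after QC:

* **RIV** — consequence in {stop gain, stop loss, splice site, frameshift
  insertion/deletion} and allele frequency strictly below `rare_af_max`
  (default 0.01) in both the reference population (ExAC-role column) and
  the control cohort.
* **RDV** — every RIV, plus missense variants with M-CAP score strictly
  above `mcap_min` (default 0.025) and both allele frequencies below
  `rare_af_max`.  A missense variant with no score is never RDV-eligible;
  absence is logged, not an error, and is distinct from a score of 0.
* **NONSYN** — any protein-altering consequence (the LoF classes,
  missense, non-frameshift indels) with both allele frequencies strictly
  below `nonsyn_af_max` (default 0.1).  This tier feeds SKAT.

All threshold comparisons are strict ("less than" / "more than"), so a
variant at exactly 0.01, 0.1 or 0.025 does not qualify.  Tiers are nested
by construction: RIV ⊆ RDV ⊆ NONSYN for any configuration with
`rare_af_max ≤ nonsyn_af_max`, and tightening `rare_af_max` can only
shrink RIV/RDV.

**QC.** The source filters ("minor allele frequency thresholds, quality
metrics, Hardy–Weinberg equilibrium") are named but unparameterised in
the field's reports, so this package fixes explicit, configurable
conventions: call rate ≥ 0.9 (the proxy for unspecified quality metrics)
and a control-cohort exact Hardy–Weinberg test at α = 1e-6.  The HWE test
is the standard two-sided exact conditional test: conditioning on the
observed allele counts, it sums the probabilities of all heterozygote
counts (of matching parity) no more probable than the observed one; the
distribution is built by a normalised recurrence, stable for cohort-scale
totals, and is verified against exact-rational enumeration in the tests.

## Carrier collapsing and the 2×2 conventions

The collapsing unit is the **carrier**: a sample with ≥ 1 qualifying
alternate allele in the gene's tier set; a sample carrying several
variants counts once, and missing genotypes count as non-carrier.  Genes
with fewer than `min_gene_count = 5` qualifying carrier-observations
(case + control (sample, variant) pairs) are flagged ineligible for the
association scan but retained for the filter-based ranking.

For the carrier/non-carrier × case/control table (a, b, c, d):

* **p-value** — Pearson 1-df χ², `χ² = N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`,
  with no continuity correction and no small-expected-count fallback;
  tables with no discordance return p = 1.
* **odds ratio** — raw cross-product `ad/bc` when all four cells are
  positive; when any cell is zero, 0.5 is added to all four cells first
  (Haldane–Anscombe).  The OR is always reported on the multiplicative
  case-vs-control scale.

Both conventions were confirmed against an independent brute-force oracle
before being frozen: together they reproduce every published OR (to one
decimal) and p-value (to printed significant digits) of the motivating
study from its printed carrier counts — e.g. (6, 1) carriers gives
OR 59.7, p 5.08e-12 and (3, 0) gives OR 68.1, p 8.36e-8 with the
reference margins.  One caveat is deliberate: for a control-only variant
(0 case / 1 control carriers), the Haldane convention yields OR ≈ 3.2,
which matches two of the three published rows with those counts; the
third published appearance of the same configuration (printed once as
−3.1 and once as 0.31, the reciprocal) is treated as a reporting slip and
the consistently oriented value is used throughout.

Significance tiers are fixed, not data-dependent: exome-wide at
p < 2.5e-6 (≈ Bonferroni over 20 000 genes) and suggestive at p < 1e-3.
P-values below 1e-300 are floored for display only; the computed floating
value is retained internally.

The **filter-based ranking** sorts genes by RIV case-carrier count
(descending), breaking ties by p ascending and then gene symbol, keeps
the top 10 and flags nominal significance (p < 0.05).  The tie-break is a
convention of this package; published top-10 lists do not state one.

The **per-sample burden summary** counts carried RIVs per sample and
compares groups with a two-sided Wilcoxon rank-sum test (normal
approximation with tie correction, no continuity correction), reporting
medians and linear-interpolation quartiles per group.

## SKAT

The tertiary test is written from scratch.  With binary phenotype `y`,
intercept-only null fit `μ̂ = n_case/n` (no covariates are modelled),
residuals `r = y − μ̂` and per-sample variance `v = μ̂(1−μ̂)`:

    Q = rᵀ G W² Gᵀ r

where `G` is the gene's n × m dosage matrix (missing dosages mean-imputed
per variant) and `W = diag(w_j)` with `w_j = Beta(1,25)` density at the
cohort minor allele frequency of variant j — the method's standard
weights, computed over cases and controls pooled.  Under the null, Q is a
mixture `Σ λ_k χ²₁` with λ the eigenvalues of `W Gᵀ P₀ G W`; for the
intercept-only null `P₀ = v(I − 11ᵀ/n)`, so the matrix is the
weight-scaled centred Gram matrix and only an m × m eigenproblem is ever
solved.  Eigenvalues below 1e-10 × the largest are truncated.

The mixture tail probability is computed by numerical inversion of the
characteristic function (Imhof's integral) with adaptive quadrature.  A
single eigenvalue is handled in closed form (a scaled 1-df χ²).  The
integrator's result is accepted when its error estimate certifies a
few-percent relative accuracy (the realised error is typically orders of
magnitude smaller; the tests pin it against a Monte-Carlo mixture
sampler); otherwise the moment-matching Liu–Tang–Zhang approximation is
used and the result is tagged `liu_fallback`.

**Binary-trait calibration.**  The Gaussian-score mixture understates
the tail for a binary trait, noticeably so at this cohort's 9.5% case
fraction: measured over 12 000 null genes, the pure asymptotic tail
gives a type-I rate of ≈ 0.0024 at nominal α = 0.001.  The default
p-value is therefore a hybrid calibrated on the exact conditional
(label-permutation) null, under which the fitted case probability is
invariant because the case count is fixed:

* genes with at most 10 carriers — **exact conditional enumeration**:
  Q depends only on the case/control status of the c carrier samples,
  so the 2^c configurations are enumerated with hypergeometric weights
  and the one-sided p is a finite sum (the deterministic limit of
  efficient resampling, no Monte-Carlo error);
* larger genes — **moment adjustment**: a shared matrix of 2000
  permuted residual vectors (fixed internal seed, so results are
  deterministic) gives the permutation mean, variance and excess
  kurtosis of Q; the p-value is the tail of a χ² with
  df = 12/kurtosis matched to those moments, which restores tail
  calibration (measured 0.0495 at α = 0.05 and 0.0013 at α = 0.001
  over 6000 null genes);
* `adjust="none"` recovers the pure asymptotic mixture tail.

One consequence is worth stating plainly: under exact conditional
inference, a gene observed with 6 case / 1 control carriers cannot reach
p < 2.5×10⁻⁶ — the smallest achievable exact p for a 7-carrier gene is
the hypergeometric mass of the all-case configuration (≈ 6×10⁻⁸), and a
6/1 profile has far larger mass.  Replanting the published SKAT gene
table therefore yields four of its six genes at exome-wide significance
rather than six; the published per-gene p-values in that table are
recognisably the carrier χ² statistics (a 6/1 row prints 5.08×10⁻¹² /
OR 59.7, identical to the collapsing table), which this pipeline
reproduces in its OR/χ² columns.  The type-I calibration (within the
binomial 99% CI of α at α ∈ {0.05, 0.001} over 2000 null genes; QQ slope
within [0.9, 1.1]) is asserted in the acceptance tests.

**Single-variant p-values** use exact conditional enumeration
("efficient resampling") when the carrier count is ≤ 10: conditional on
the total carrier count c, the case-carrier count K is hypergeometric,
and the two-sided p sums P(K = k′) over all k′ whose squared score
(k′ − cμ̂)² is at least the observed one.  Above the cutoff the
asymptotic mixture tail is used (logged).  A Bonferroni column
(min(1, p·m)) accompanies the per-variant output.

## Synthetic cohorts

The generator emulates the features the analyses are sensitive to:

* cohort margins default to 146 cases / 1395 controls;
* background genotypes are Binomial(2, MAF) per sample and variant, with
  MAFs from a heavy-tailed Beta(0.3, 100) spectrum clipped to ≤ 0.095
  (≤ 0.007 for LoF classes, safely inside the rarity threshold so
  sampling noise rarely pushes a variant over it);
* the LoF MAFs are rescaled by a capped fixed-point iteration so the
  expected per-sample RIV count equals `background_riv_burden` (default
  10.5, between the reference cohort's reported medians of 10 and 11);
  the per-sample count is then approximately Poisson(10.5), which puts
  both group medians in [9, 12] across seeds — the reported IQRs (6–14)
  are somewhat wider than Poisson, i.e. real burden is overdispersed,
  which this generator does not model;
* consequence classes follow a configurable mix (≈ 21% LoF by default);
  missense variants receive an M-CAP score from a mixture with
  P(score > 0.025) = 0.5, with 5% of scores missing;
* reference-population AFs equal the cohort MAF up to log-normal noise
  (σ = 0.2), clipped to the class cap.

**Planting is exact, not in expectation.**  Gene-level planted effects
choose the requested numbers of distinct case and control carriers by
combinatorial assignment and spread them round-robin over (default) five
synthetic variants; variant-level plants realise exact per-variant counts
with disjoint carrier sets within a gene, so gene-level counts are the
per-variant sums.  Infeasible targets fail before any sampling.  The
replanting scenarios keep the background free of LoF variants so the
planted counts are the only inactivating-variant signal (background
missense/synonymous variants still exercise QC, tiering and SKAT).

Variants are simulated unlinked (no LD) and without population
stratification or relatedness; passing tests therefore demonstrate
correctness of the statistics and plumbing, not robustness to those
real-data complications.  Identical scenario + seed yields byte-identical
VCF/TSV output.

## Numerical and design choices

* Coordinates are 1-based VCF convention; indels are anchored-base style;
  multi-allelic sites are decomposed at read time (dosage of ALT k =
  number of GT alleles equal to k; any missing allele makes the genotype
  missing; phased separators are treated as unphased).
* Percentages in result tables are computed from counts at write time
  (never stored) and rounded half-even to one decimal.
* The problem sizes used by the tests and the acceptance script — 2000
  null genes for SKAT calibration, 20 seeds for burden calibration, 40
  background genes in replant scenarios — were chosen as the smallest
  sizes at which the binomial/Monte-Carlo tolerances quoted above are
  meaningful.
* Library division of labour: VCF parsing is cyvcf2; tabular I/O is
  pandas; χ², hypergeometric, Beta-density weights, rank-sum test and
  quadrature are scipy.  The contributions implemented here by hand are
  the tiering rules, the 2×2 conventions, the exact HWE test, the SKAT
  statistic/eigenstructure/tail inversion, the exact-resampling
  single-variant p, and the generator.

## Known limitations

* No covariate adjustment (the null model is intercept-only), no Firth or
  exact logistic alternatives, and no SKAT-O; these are out of scope.
* The moment adjustment estimates kurtosis from 2000 permutations; its
  df estimate is noisy when the permutation null is nearly Gaussian, in
  which case the adjustment is skipped (the asymptotic tail is then
  appropriate anyway).
* The Imhof inversion loses relative accuracy in the extreme tail
  (p ≲ 1e-12); such values are orders of magnitude below every decision
  threshold, and the Liu fallback used there is known to be conservative
  in the far tail.
* The generator's burden is equidispersed (Poisson-like); real cohorts
  are overdispersed.
* The HWE filter is applied to controls only, mirroring its use as a
  genotyping-quality screen.
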