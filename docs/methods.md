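# Methods

## Data model

An MS-AFLP scoring table has one row per (accession, assay) with binary
presence/absence calls over named bands. Bands are grouped by primer
combination `a`–`i` and indexed heavy→light within a primer. Each
accession contributes exactly two rows: the EcoRI+HpaII digest (`HPA`)
and the EcoRI+MspI digest (`MSP`). The packaged accession table carries,
for each of the 22 clonal sources, its genotype (7 labels), the BF
exhibition category on the ordinal scale High=6, Medium to High=5,
Medium=4, Low to Medium=3, Low=2, No=1, and the clonal age in decades
since the clone was first used as a budwood propagation source.

The published per-primer band counts (120, 136, 125, 161, 114, 214, 133,
121, 124) sum to 1248, while the text also quotes "1251 fragments" and a
grand total of 24,794 scored bands (= 22 × 1127, which matches none of
the locus counts). These inconsistencies cannot be resolved from the
published record; the package uses the per-primer counts (1248) for the
synthetic default and quotes the published numerators/denominators
verbatim where it reproduces printed percentages.

## Epigenotyping

HpaII is blocked by internal-C methylation of CCGG while MspI cuts it,
so the joint banding pattern encodes four states: (1,1) demethylated,
(1,0) hemimethylated, (0,1) internal-C methylation, (0,0) full
methylation. The (0,0) pattern is scored as full methylation by default
(the choice behind the published fraction table); because absent/absent
can also mean loss of the restriction target, `classify_matrix(...,
absent_as_missing=True)` treats it as missing instead.

A locus is methylation-susceptible (MSL) when the fraction of accessions
in a non-demethylated state exceeds an error threshold, default 0.05 —
the usual MSAP-style tolerance for scoring error; the source analysis
names the MSAP package but not its threshold. MSL loci with at least two
distinct states across accessions are flagged polymorphic.

BF/NBF dichotomization defaults to BF iff score ≥ 4 ("Medium" and
above). This is the only threshold that splits the 22 accessions 11/11,
which is what the published 2×2 margins imply; it is configurable.

## Association statistics

The genome-wide 2×2 uses raw cell aggregation over all (band, accession)
pairs. φ = (n₁₁n₂₂ − n₁₂n₂₁)/√(n₁.n₂.n.₁n.₂); Pearson χ² is computed
without Yates correction by default and satisfies χ² = Nφ² exactly on
2×2 tables. "Correlation" in the mosaic analysis is implemented as φ (it
reproduces the published 0.064 on the printed counts). Conditional
independence on 2×2×K strata uses the Cochran–Mantel–Haenszel statistic
(statsmodels), continuity-corrected by default; note the single-stratum
CMH equals the corrected χ² only up to the (N−1)/N factor. Concordance
between accessions is Kendall τ_b (tie-adjusted) on the binary
methylated/unmethylated profiles, delegated to
`scipy.stats.kendalltau(variant="b")`; an exhaustive pair-enumeration
oracle in the test suite verifies it on every pair of non-constant
binary vectors up to length 8.

## Ordination

Default distance is the per-band mismatch proportion (simple matching):
joint absence of methylation is informative agreement here, since
"demethylated" is itself a state. PCoA is the classical construction
B = −½JD²J with eigendecomposition; coordinates are eigenvectors scaled
by √λ for positive eigenvalues, and negative eigenvalues are reported
unchanged (no Cailliez/Lingoes correction) for transparency. UPGMA uses
average-linkage with ties broken by the lexicographically smallest pair
of cluster labels, making output deterministic; trees are ultrametric by
construction and export to Newick. Both are cross-checked in the tests
against skbio's PCoA and scipy's average-linkage cophenetic matrix.

## Bayesian log-linear model selection

Record-level data (one record per band × accession, with `deMet01`,
`ChronoAge`, `GenotypeN`, BF score) are cross-classified into cells
defined by the distinct accession covariate profiles (BF score,
genotype, age) crossed with both `deMet01` levels, retaining structural
zero counts. Cell counts are Poisson with a log-linear predictor over a
downward-closed set of terms from {deMet01, ChronoAge, GenotypeN};
ChronoAge enters as a continuous cell covariate, factors are
treatment-coded against their first level. Restricting cells to
observed covariate profiles (rather than an abstract full cross over BF
level × genotype) keeps the table complete on the design's support;
profiles that no accession realizes have no defined age and are omitted.

Priors: flat on the intercept (shared by all models); non-intercept
coefficients get a unit-information g-prior N(0, g·C·(Xc′Xc)⁻¹) with Xc
the centered design and C the number of cells, and the generalized
hyper-g hyper-prior g/(1+g) ~ Beta(1, (a−2)/2). The default a = 4 makes
the shrinkage factor uniform; the source names the prior family but not
its hyper-parameters.

Sampler: per iteration (i) a full-vector random-walk Metropolis update
of the coefficients, preconditioned by the MLE curvature and scaled
2.38/√d; (ii) a log-scale random walk on g (sd 0.8); (iii) a
reversible-jump move to a candidate model one term away (add/delete,
hierarchy-respecting), with the destination model's full coefficient
vector proposed from its Laplace approximation (MLE mean, curvature
covariance inflated ×1.3). Defaults mirror the study settings: 12,500
iterations, burn-in 2,500, no thinning. Chains are bit-reproducible
given (seed, settings, data).

Validation oracle: the marginal likelihood of each model is computed
independently by a Laplace approximation over coefficients at each node
of a trapezoid grid in log g (default 320 nodes on [−30, 25]). The grid
is in log g deliberately: when the data carry little signal the
posterior of g concentrates several orders of magnitude below 1, and a
grid on the shrinkage factor g/(1+g) misses that mass (an early version
did exactly this and disagreed with long chains by ~0.03 in model
probability; the log-g grid agrees with brute-force dense integration on
small problems and with 500k-iteration chains to ~0.002). The acceptance
suite compares sampler model probabilities to this oracle over 10 seeds
within 3 Monte-Carlo standard errors, with a 0.005 floor representing
the oracle's own quadrature/Laplace precision.

Goodness of fit is the posterior-predictive p-value on the Poisson
deviance D = 2Σ[O ln(O/E) − (O − E)] (0·ln 0 = 0): the fraction of
retained draws whose simulated replicate table has deviance ≥ the
observed table's at the same parameters, ties counting toward p_B (so a
saturated zero-deviance fit gives p_B = 1). Terms are ranked by the
count-weighted variance of their linear-predictor contribution across
records, rank 1 = largest.

The source analysis reports exactly "five models … twenty-eight
parameters" for the three-factor frame and "three models … four
parameters" for the Nonpareil frame; no enumeration rule stated there
reproduces those counts (hierarchical enumeration gives 9 models with
forced main effects for three factors), so the module logs its own model
count and does not force agreement. Its reported p_B = 1 alongside a 0%
RJ acceptance indicates a chain that never left the saturated model;
this is noted, not emulated.

## Effects

The record-level BF fit is a binomial-logit GLM (statsmodels IRLS) on
the dichotomized score; separation is detected (fitted probabilities
pinned at 0/1 with exploding coefficients) and raised as an error rather
than silently returned — on the Nonpareil-only synthetic frame the
dichotomized response is completely separated by age, reproducing the
convergence trouble the original dichotomous fits reported. McFadden's
adjusted pseudo-R² is 1 − (ℓ_model − k)/ℓ_null. Odds ratios exponentiate
contrast-weighted coefficient sums; the published value 0.90489 for the
methylated state equals exp(−0.105934 + 0.005994) = exp(−0.099940),
confirming that the printed "−0.099994" log-odds change is a typo for
the sum of the published posterior means. The published phrase "one-year
increase" is implemented as one ChronoAge unit (a decade in the
accession table) because that reproduces the printed odds ratios
exactly; the unit label is inconsistent in the source. Effect curves are
linear in age on the log-odds scale per methylation level; the slope
difference equals the interaction coefficient identically.

## Synthetic generator

The generator emulates the study's shape only: the 22 accessions (with
their real scores and ages), the nine primer combinations with the
published band counts, and two assay rows per accession. Methylation of
each (band, accession) cell is Bernoulli with logit = per-band baseline
(Normal(0, 1.5) across bands) + 0.09·(BF score − mean) + 0.02·(age −
mean) + genotype offset (default 0). The BF coefficient was chosen so
the synthetic 2×2 shows the published direction and order of magnitude
(BF accessions a few percentage points more methylated than NBF, φ of a
few hundredths); the band-baseline spread makes most loci polymorphic
MSL, matching the published 91% polymorphism qualitatively. Conditional on
methylation, the state is hemi/internal/full with probabilities (0.16,
0.19, 0.65), the ratios of the published fraction table. Calls are then
derived by inverting the isoschizomer scheme, and independent HPA/MSP
call errors (rate 0.02) deliberately create state misclassification to
exercise the MSL error threshold.

What the generator does not emulate: gel mobility and fragment sizes,
primer sequence specificity, linkage between bands, per-accession band
total quirks (the unexplained 24,794), or any biological mechanism of
BF. Passing recovery tests therefore demonstrates correctness of the
inference machinery under the stated generating model, not biological
validity on real gels.

For HPD-coverage checks of the posterior, data are instead drawn from a
known log-linear cell model (`simulate_loglinear_frame`): band-level
logistic generation places the implied log-linear truth slightly outside
the Poisson family (softplus curvature in the row means), which would
confound coverage with misspecification bias. The recovery study plants
a deMet01 × ChronoAge interaction of 0.04 on the log scale at 6,000
records over the Nonpareil accessions — an effect size chosen in an
initial power check so that detection (posterior inclusion > 0.9) is
unambiguous at that sample size — and requires detection and 95% HPD
coverage of the truth in at least 18 of 20 seeded replicates.

## Problem sizes and numerics

Test and acceptance runs use the full 12,500-iteration default chains on
small tables (4–18 cells), 10-seed oracle comparisons on 2×2 and 2×2×2
problems at ~500–2,000 counts per cell, and 20-replicate recovery runs
at 6,000 records; the whole suite completes in about two minutes on one
CPU. Linear predictors are clipped at ±500 before exponentiation;
Newton/IRLS fits add a 1e-10 ridge and stop at relative log-likelihood
change < 1e-10 (max 100 iterations); HPD intervals use the Chen–Shao
shortest-interval sweep and require ≥ 100 draws.

## Known limitations

- The published Tables of posterior summaries and the pseudo-R² values
  are not reproducible from data because the raw band matrix was never
  deposited; the package reproduces the exactly recomputable worked
  examples and validates the machinery on synthetic data instead.
- The published group-conditional fraction table and the genome-wide
  2×2 counts cannot be reconciled under any single denominator the
  source defines (the 2×2 sums to 24,792, the percentages use 24,794);
  both computations are exposed and neither is forced to agree.
- "Nonpareil (nine clones)" cannot be reconstructed from the accession
  table (7 'Nonpareil' labels plus 4 Stukey polyembryonic derivatives);
  the Nonpareil frame defaults to the 7 genotype-labelled accessions.
- The RJ sampler's Laplace-based independence proposals are efficient on
  the small cell tables this analysis produces but would need tuning for
  tables with hundreds of cells or near-degenerate MLEs.
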