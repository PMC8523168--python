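# Methods

## The inference chain

`invasim` re-implements, as a tested pipeline, an inference chain linking
three layers of observation on a set of bacterial communities grown in
laboratory microcosms:

1. **Starting composition** — 16S amplicon OTU counts per community,
   with taxonomy and a rooted phylogeny over the OTUs and the two
   invader strains.
2. **Realised phenotype** — productivity proxies (flow-cytometry cell
   yield, MicroResp respiration) and metabolic measurements (ATP, four
   extracellular enzyme activities) at days 7 and 14 of growth.
3. **Invasion outcome** — survival of two lux-tagged *Pseudomonas*
   invaders (*P. fluorescens*, *P. putida*) at 24, 96 and 168 h
   post-invasion, measured as induced luminescence in four technical
   replicates and converted to cells/mL through a growth-assay
   calibration.

The scientific question is a mediation question: how much of the effect
of starting composition (C) on invasion resistance (I) flows through
realised productivity (P)?

## Preprocessing

*OTU filtering.* OTUs present in fewer than 10 communities or with fewer
than 100 reads in total are removed, then communities with fewer than
10,000 remaining reads are removed. All thresholds are strict
inequalities (exactly 10 communities / 100 reads / 10,000 reads are
kept); the OTU filter precedes the community filter, and the whole
operation is idempotent.

*Luminescence calibration.* Plate counts are regressed on luminescence
on the log10–log10 scale by OLS over the log phase of a growth assay.
When no log-phase window is supplied, the contiguous window of assay
hours maximising R² over at least four usable points is selected and
reported with the fit — "log phase" is a property of the assay, not a
fixed clock range. Conversion is `cells = 10^(a + b·log10 lux)` with 0
mapping to 0.

*Detection threshold.* The threshold is the maximum luminescence of
sterile-medium blanks (12 lumens in the emulated design). Replicates are
flagged below-detection **on the lux scale, before conversion**, because
the calibration is nonlinear and sub-threshold readings are background
regardless of their converted value. Replicates are converted first and
averaged second (the calibration is nonlinear in lux); a mean is flagged
only when every contributing replicate was flagged.

*Transforms.* The response (invader survival, cells/mL) is
log10(x + 1). Explanatory phenotype and abundance variables are
log10(x), with zeros mapped through half the smallest positive observed
value of the column — a +1 pseudocount would distort enzyme activities
measured in fractions of mg/mL. The three diversity variables enter
untransformed.

## Diversity metrics

Gini–Simpson diversity `1 − Σp²`; Rao's quadratic entropy
`Q = Σᵢⱼ pᵢpⱼdᵢⱼ` over cophenetic (path-length) distances; and the
abundance-weighted invader–community distance `Σᵢ pᵢ·d(invader, OTUᵢ)`.
By default the cophenetic distances are divided by their maximum before
Rao's Q, bounding Q in [0, 1] and making Q equal Gini–Simpson under
equal distances; raw branch-length units are available
(`normalize=False`) and the choice is recorded in output metadata.
Relative abundances are computed from filtered counts without
rarefaction.

## Dimensionality reduction of composition

Seven representations are computed and compared: taxonomic aggregation
at genus/family/order/class/phylum (missing labels pooled into an
explicit "unclassified" column; row sums conserved), principal
coordinates of the Jensen–Shannon divergence matrix, and functional
groups from a signed co-occurrence network.

*JSD + PCoA.* The divergence (natural log, not its square root) is not
Euclidean, so the Gower-centred matrix has negative eigenvalues; these
are dropped with a logged warning rather than corrected (no Cailliez
constant), and each axis' sign is fixed so its largest-magnitude loading
is positive. Five axes are kept by default; the full eigenvalue table is
emitted so the scree inspection can be replicated by hand.

*SparCC.* Basis correlations are estimated from log-ratio variances
`t_ij = var(log x_i/x_j)` (pseudocount 1 on zeros) via the linear system
for basis variances, with up to 10 iterations excluding the strongest
pair above |r| = 0.1. Pseudo p-values are two-sided exceedance
proportions over datasets with independently permuted columns (100 by
default; the attainable minimum is 1/(B+1), so B ≥ 100 is required for
the p < 0.01 edge rule to ever fire). Edges require |r| > 0.2 **and**
p < 0.01, both strict; positive correlations are aggregation links,
negative ones segregation links.

*Functional groups.* Nodes sharing the same typed links to the same
neighbours occupy the same network position. Similarity is the Jaccard
index over typed neighbour sets (a shared neighbour counts only when
both links carry the same sign; a linked pair counts themselves as
shared), clustered by average linkage on 1 − similarity. The cut
maximises the total partition density
`D = (2/M) Σ_c m_c(m_c − n_c + 1)/((n_c − 2)(n_c − 1))` over clusters of
at least three nodes. Ties on D are broken first by partition
**stability** — the longest run of merge heights over which the
partition persists — then by fewest clusters, then lexicographically.
The stability criterion is needed because sparse graphs (e.g. stars)
have D = 0 for every cut, where "fewest clusters" alone would collapse
everything into one group; persistence picks the partition the
dendrogram actually supports.

Groups with ≥ 3 members become features (mean count across member OTUs
per community); named merge rules may rescue sets of smaller groups as a
single extra feature; everything else pools into a `remainder` feature
(mean over non-retained OTUs, 0 when empty).

Reductions are compared by composition-only random forests per invader ×
time point; the emitted table flags the Pareto-efficient set (no other
reduction has both ≥ pseudo-R² and ≤ features) and pre-selects the
Pareto point with the best mean pseudo-R², while the full table allows a
manual override.

## Random-forest screening

Regression forests (500 trees, `mtry = ⌊p/3⌋`, bootstrap resampling)
regress each of the six survival endpoints on the composition features
plus the 14 phenotypes plus the three diversity variables (37 columns
with a 19+1-group representation). Importance is out-of-bag permutation
importance: per tree, the OOB MSE increase when one feature's OOB values
are permuted, reported both as the mean relative increase in percent
(`inc_mse_pct`) and normalised by its standard error over trees
(`inc_mse_norm`); comparisons use the raw variant to avoid
division-by-small-SE artifacts. Pseudo-R² is `1 − MSE_oob/var(y)` from
pooled OOB predictions; it can be negative on null data.

## Structural equation models

Three latent variables: Composition (indicators: the retained group
features plus Simpson diversity), Productivity (cell yields at days 7
and 14), Invasion (the six survival endpoints). Three structural
hypotheses: NoMediation (C→I), PartialMediation (C→P, P→I, C→I),
CompleteMediation (C→P, P→I); Complete is nested in Partial with exactly
one fewer parameter.

Estimation is normal-theory ML: minimise
`F = log|Σ(θ)| + tr(SΣ⁻¹) − log|S| − p` with an analytic gradient
(L-BFGS-B). Identification is by unit first loading; latent disturbances
and indicator residual variances are free, no residual covariances.
Numerical choices:

- The optimisation runs on the correlation-scaled covariance (the ML
  discrepancy is invariant to diagonal rescaling for this model class),
  which makes convergence independent of indicator units; reported raw
  loadings and paths are mapped back to the anchor-indicator metric.
- Structural paths start at factor-proxy regression estimates computed
  from block-mean correlations. Zero starts can strand the optimiser in
  a no-effect local basin when a latent is weakly measured; the proxy
  start lands in the correct basin.
- Up to 5 jittered restarts on non-convergence; variances are bounded
  below at 1e-10 and a fit touching that bound is flagged as a Heywood
  case (warning, not an error).
- A near-singular sample covariance receives a ridge of
  `1e-6·mean(diag S)` with a logged warning (many group features are
  compositionally collinear).

Fit statistics: `χ² = (n−1)·F` at the optimum;
`df = p(p+1)/2 − q`; AIC = −2·loglik + 2q with
AICc = AIC + 2q(q+1)/(n−q−1), where n counts communities and q all free
parameters; CFI against the independence baseline. The
Partial-vs-Complete likelihood-ratio test uses `χ²_C − χ²_P` on 1 df.

*Mediation decomposition.* From the standardised Partial solution:
indirect = (C→P)·(P→I); total composition effect = direct C→I +
indirect; total productivity effect = direct P→I + indirect; proportion
mediated = indirect / total composition effect (NaN when the total is
0). A "printed" variant reproduces the two-decimal arithmetic in which
published decompositions of this design are typically quoted: the
indirect effect is rounded to 2 dp before entering the ratio, and the
ratio uses the **total** P→I effect as denominator. Both are always
reported; parameter-recovery checks use the model-based definition.

Modification indices are deliberately not implemented: post-hoc residual
correlations would have to be added per model, which breaks the fairness
of a three-way comparison.

## Censoring sensitivity analysis

Below-detection survival values may be background noise. The analysis
shuffles the censored values among themselves (sampling without
replacement), refits the three SEMs per shuffled dataset (999
permutations by default; warm-started from the unpermuted solution), and
tallies best-model frequencies and mean AICc shifts. Shuffling is
column-wise (within each invader × time endpoint) by default because
endpoints differ in invader and scale; a global-pool mode is available.
Shuffling acts on the averaged, calibrated cells/mL values entering the
SEM.

## The synthetic-data generator

The generator emulates the study design end-to-end: 680 communities, 200
OTUs in 10 planted groups of 20, library size 20,000, two invaders ×
three time points × four replicates, a 12-lumen detection threshold.

*Composition.* Each group draws a per-community log-abundance factor;
OTUs mix the group factor (weight √ρ, ρ = 0.8 within-group correlation)
with private noise; expected proportions are the softmax of log
abundances and counts are multinomial. The driver group's factor doubles
as a community-level compositional axis: other groups load on it with
weights ±0.25…±0.35, strong enough that group-abundance features share a
common factor (as real communities organised along an ecological
gradient do) but weak enough that cross-group OTU correlations stay
below the SparCC edge threshold, so the planted partition remains
recoverable. The composition score C is the standardised log mean
expected abundance of the driver group.

*Causal structure.* Latents are standardised; path coefficients default
to the standardised scale C→P = 0.47, P→I = −0.33, C→I = −0.13 (planted
proportion mediated 0.544). Cell yields load on P at 0.8, respiration at
0.6, ATP at 0.2, enzymes at 0; the six survival endpoints load on I at
0.8 with per-time-point location shifts so survival declines with time
and *P. putida* survives less well than *P. fluorescens*.

*Measurement chain.* Endpoint cell densities pass through the inverse of
the per-invader calibration (a, b chosen so 12 lumens converts to
detection limits near 6.3×10³ and 1.1×10⁴ cells/mL), acquire log-normal
replicate noise (CV 0.2, mean-one), and are left-censored: sub-threshold
lux is replaced by a uniform draw on (0, threshold), emulating
sterile-blank background rather than zeros so that the sensitivity
analysis sees realistic sub-threshold variation. Everything is
byte-identical under a fixed seed.

*What the generator does not emulate.* Sequencing error, chimeras,
ecological dynamics during growth, non-normal latent distributions, and
OTU-level phylogenetic signal in abundances beyond the clade/group
correspondence. Passing tests therefore demonstrate that the chain of
estimators recovers a known causal structure from data with this noise
anatomy — not that the estimators are robust to every failure mode of
real amplicon data.

## Known limitations

- **Latent-composition attenuation.** In the end-to-end pipeline the
  Composition latent is the common factor of the group features plus
  Simpson diversity. That factor is correlated with, but not identical
  to, the planted driver score, so the standardised C→P and C→I paths
  are attenuated relative to the planted coefficients. The proportion
  mediated — a ratio of two such paths — is far less affected, but with
  the small planted direct effect the estimated total composition effect
  can approach zero, making the single-run end-to-end ratio volatile
  (the acceptance script therefore also reports recovery on data drawn
  directly from the latent model, averaged over datasets).
- **Ratio estimation near full mediation.** At a planted proportion of
  1 the direct path is exactly 0 and the recovered proportion is
  `1 − ĉ′/total`; the sampling SD of ĉ′ (~0.05 at n = 680 with loadings
  0.8) puts a floor of roughly ±0.1–0.15 on the ratio's spread
  regardless of effect size.
- **AIC-family selection between nested models differing by one
  parameter** has an irreducible error rate: under the smaller model's
  truth the larger model wins whenever the χ²₁-distributed likelihood
  improvement exceeds ≈ 2, i.e. ~16% of datasets.
- SparCC pseudo p-values use column permutation, not the original
  bootstrap-with-resampling; with B shuffles the smallest attainable
  p-value is 1/(B+1).
- The functional-group detector is a deliberately simple network
  position clustering (typed-neighbour Jaccard + average linkage +
  partition-density cut); the partition step is pluggable for users who
  want a different community-detection method.

## Problem sizes used in tests and the acceptance script

The test suite exercises small synthetic studies (60–80 communities,
30–40 OTUs) for pipeline mechanics, and full-size latent-model datasets
(n = 680) for the statistical recovery checks (20 seeds per setting).
The acceptance script runs the complete pipeline once at the full study
scale (680 communities, 200 OTUs, 500 trees, 99 sensitivity
permutations) plus a 10-dataset latent-model recovery average.
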