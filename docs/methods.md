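# Methods

`fvtqtl` implements a genotype-to-phenotype pipeline for function-valued
growth traits in a biparental recombinant inbred line (RIL) population:
hierarchical Bayesian estimation of logistic growth-curve parameters from
longitudinal leaf measurements on a thermal-time axis, shrinkage genotype
means, QTL interval mapping of the curve parameters, QTL-by-environment
tests, and prediction of whole growth curves for unseen genotypes from
additive QTL effects. This note records the model, its assumptions, the
defaults, and the choices made where the design was genuinely open.

## Growth model and thermal time

Leaf size follows the logistic law

    dL/dt = r · L · (1 − L/Lmax),    L(0) = L0,

with t in accumulated degree days (DD) since germination, giving the
closed form L(t) = Lmax / (1 + ((Lmax − L0)/L0)·e^(−r·t)). Parameters:

| parameter | meaning | units | typical default (leaf width) |
|---|---|---|---|
| r | intrinsic growth rate | 1/DD | 0.02 |
| Lmax | asymptotic leaf size | mm | 60 |
| L0 | size at germination | mm | 2 |

Two duration traits are derived in closed form: the inflection time
iD = ln((Lmax − L0)/L0)/r, where growth switches from accelerating to
decelerating, and d, the time to a stated fraction of final size
(fraction 0.95 by convention). Both are computed by exact inversion of
the logistic rather than curve scanning. When L0 ≥ Lmax/2 the inflection
precedes the observation window; iD is reported as 0 with a warning
rather than as a negative time.

A note on units: with this parameterization r has units 1/DD, although
rate-of-growth parameters for size curves are often loosely quoted in
mm/DD. The logistic form above is the only reading consistent with an
interior inflection point, so it is what the package implements
throughout.

Thermal time accumulates by the simple-average method,
max(0, (tmin + tmax)/2 − base), with a base temperature of 0.96 °C, a
*Brassica rapa*-specific value. The simple-average method with truncation
at zero was chosen over hourly integration for determinism and
testability; accumulation is non-decreasing and invariant to splitting a
temperature series.

## Hierarchical Bayesian curve fitting

For one trait × treatment × year stratum the three-level model is, with
θ = (log r, log Lmax, log L0) componentwise:

* y_ijk ~ N(L(t_ijk; θ_ij), σ²) — measurement k of plant j of genotype i;
* θ_ij ~ N(g_i + β·a_i, τ_p²) — plant level; a_i is the genotype's
  centered photosynthetic capacity (A_max, μmol m⁻² s⁻¹) when supplied,
  so carbon-resource differences shift the plant-level prior means and
  the residual genetic signal in g_i is interpreted net of A_max;
* g_i ~ N(μ, τ_g²) — genotype level;
* μ ~ N(m0, 2²) with m0 set from the data range (e.g. the log of the
  maximum observed size for log Lmax).

Parameters are sampled on the log scale, which enforces positivity of r,
Lmax, L0. Variances carry weakly informative inverse-gamma priors
(IG(2, 0.01) for the log-scale hierarchy variances; IG(0.01, 0.01) for
σ² so the data dominate the residual variance). The covariate slope β has
a N(0, 1) prior per component and is centered before use so μ stays
interpretable. Strata (trait, treatment, year) are always fit
independently; whether to pass the A_max covariate is a per-fit option,
since the covariate may only exist for a subset of seasons.

Sampling is single-chain Metropolis-within-Gibbs. Plant-level curve
parameters move by component-wise random-walk Metropolis (component-wise
moves mix far better than joint isotropic proposals along the strong
r–L0 posterior ridge); everything else — genotype means, the global mean,
β, all variances — is a conjugate Gibbs update. Proposal scales adapt
toward 30% acceptance during burn-in only, preserving detailed balance
afterwards. Plants are initialized at per-plant nonlinear least-squares
fits (falling back to a logit-slope heuristic when the optimizer fails);
initialization affects only burn-in length, not the target distribution.

Chain-length presets: the full protocol is 500,000 iterations with
440,000 burn-in thinned 1-in-20 (3,000 retained draws); the short preset
used in simulation studies is 8,000/4,000 thinned 1-in-4 (1,000 draws).
Convergence is checked by lag-k autocorrelation, effective sample size,
and acceptance-rate diagnostics; constant (degenerate) chains are
flagged, and a median acceptance rate near zero marks the fit as
diverged.

Two 95% pointwise credible envelopes summarize each genotype: the inner
band is the percentile envelope of the genotype-mean curve over posterior
draws; the outer band is the posterior predictive for a future
observation of a new plant of that genotype (new plant-level parameters
drawn from the plant prior, residual noise added). The outer band
necessarily contains the inner band; with finite draws the percentile
estimates are clipped to preserve that nesting exactly. On simulated
data the outer band's coverage of fresh observations is near nominal and
slightly conservative at small plant counts, because it honestly
propagates the uncertainty in the plant-level variance.

## Genotype means and variance partitioning

Prior to downstream analyses each trait vector passes a single-pass
outlier rule: observations more than 3 SDs from the mean (mean and SD
from the full input) are removed and logged. The rule is deliberately not
iterated; re-running it can remove further points, so one pass is the
documented, testable contract.

Genotype means are shrinkage estimates (BLUPs) from a REML fit of a
random-intercept model with genotype and block effects. The engine
handles any set of crossed or nested random intercepts with independent
components (V = σ²_e·I + Σ σ²_k Z_k Z_kᵀ), which covers the full
variance-partition table over genotype, treatment, year, block nested in
treatment × year, and their interactions — random intercepts only, no
random slopes. In the balanced one-way case the BLUP reduces to
λ(ȳ_i − ȳ), λ = σ²_g/(σ²_g + σ²_e/m), and the REML estimates match the
closed-form ANOVA estimators.

Random effects are tested by likelihood-ratio chi-squares between REML
fits with and without the term, 1 df per dropped variance component. The
null value lies on the boundary of the parameter space, so the nominal
χ²₁ p-value is conservative; this convention is reported as-is.

## QTL mapping

Genotype probabilities along each chromosome come from a two-state hidden
Markov model (the two homozygote classes only — the population is fully
inbred, and any residual heterozygote calls are treated as missing), with
Haldane transition probabilities on the cM scale and a symmetric
genotyping-error emission (default 0.001). Map distances are interpreted
on the RIL scale, i.e. already expansion-corrected, which avoids modeling
selfing generations. The scan evaluates markers plus a step grid (default
1 cM).

Haley–Knott regression scores each position by regressing genotype means
on expected allele dosage: LOD = (n/2)·log10(RSS0/RSS1). At fully
informative markers this equals exact single-marker regression.
Genome-wide significance uses permutation of the phenotype-to-line
assignment (default 10,000 permutations at quantile 0.95; 0.90 for the
prediction pipeline below; reduced counts in tests), seeded and
reproducible.

The multi-QTL search iterates: scan conditional on the current model
(implemented by residualizing on current-model dosages — regression-based
throughout, trading exactness for speed), add the highest new peak above
threshold, refine each locus position holding the others fixed, stop when
nothing passes. Ties at equal LOD break deterministically to the lowest
chromosome then lowest cM. The final multi-locus fit reports, per locus:
drop-one LOD, additive effect (half the fitted BB−AA difference),
direction (+1 when the first parent's allele increases the trait), PVE =
100·(1 − 10^(−2·LOD/n)), and a 1.5-LOD support interval from a
conditional scan (expanded to the flanking evaluated position when the
interval boundary sits strictly above the drop line). When the same
trait's QTL from different environments colocalize — overlapping 1.5-LOD
intervals, same effect direction — reporting collapses them to the
highest-LOD representative so a locus is not tested repeatedly.

## QTL-by-environment interactions

Each mapped marker is tested one at a time in a fixed-effect crossed
model of trait on marker genotype × treatment × year. Terms are judged by
Type III F statistics, F = ((RSS_without − RSS_full)/Δdf)/(RSS_full/df_resid),
under sum-to-zero contrasts — enforced, not optional, because Type III
marginal tests are not meaningful under treatment coding. Terms made
inestimable by empty cells (e.g. a three-way term when one treatment is
unobserved in a year) are flagged and skipped. The tests accept either
plant-level records or genotype means; the denominator df makes the
choice visible in the output.

## Prediction of unseen genotypes

A held-out genotype's parameter is predicted as

    x_i = x̄ + Σ_j direction_ij · effect_j

over the mapped QTL for that parameter, where x̄ is the training
population mean, effect_j the additive effect, and direction_ij set by
the allele the genotype carries at the locus's nearest marker (a missing
call contributes nothing). The predicted (r, Lmax), with L0 fixed at the
population median of fitted initial sizes from the training genotypes,
defines a full logistic curve. Predictions with non-positive parameters
or Lmax ≤ L0 are counted as failures rather than clamped, keeping the
success metric honest.

The leave-k-out experiment (default k = 5, 20 rounds, mapping threshold
at the 0.90 permutation quantile — deliberately more permissive so
marginal but biologically meaningful QTL enter the predictive model)
partitions shuffled genotypes into disjoint held-out sets, so no genotype
is predicted twice. Per round everything is refit on the training
genotypes only — the measurement table is split before any fitting, so no
held-out phenotype can leak into training. Predicted curves are scored
against envelopes fit to the held-out genotypes' own plants: within an
environment, success means the curve stays inside the inner band
everywhere and marginal means inside the outer band; across environments
the outer band defines success. Success proportions are compared to
chance (0.5) by a one-sided proportion Z test with n = the pooled count
of scored genotypes, and predicted vs observed parameter means are
summarized by Pearson correlation pooled across rounds.

Because the envelopes bound the whole curve, a scalar parameter has no
band of its own. Failures are attributed by where the curve escapes:
violations only at late thermal time (t > predicted d) count against
Lmax, only at early time (t ≤ predicted iD) against r, and anything else
against both. This preserves separate per-parameter success rates while
being operationally unambiguous.

## Synthetic data

The generator emulates the target study design: 119 RILs plus two fully
homozygous parents, ten chromosomes of evenly spaced markers, two density
treatments crossed with multiple growing seasons, randomized blocks, and
5–16 sequential measurements per plant on a jittered degree-day schedule
(2–3 field visits per week converted to DD). Genotypes are a two-state
Markov walk per chromosome with Haldane recombination fractions — no
interference, matching the Haldane choice in mapping — and optional
missingness. Genotype-level parameters are additive in the QTL genotypes
(each QTL's effect is the allele-class difference, so an effect e
separates the homozygote classes by e), plus optional non-QTL genotypic
noise (`geno_sd`, needed to realize architectures where mapped QTL
explain a stated fraction of genotypic variance) and i.i.d. genotype×year
deviations — the simplest structure expressing genetic variation in
plasticity. Plant-level parameters add block effects and plant noise on
the log scale, matching the lognormal hierarchy of the fitted model, and
the A_max covariate contribution when its slope is nonzero. Measurements
are curve values plus Gaussian noise (default SD 1 mm), floored at a
small positive size.

Reflectance spectra are a smooth vegetation-like baseline (green peak,
red edge, NIR plateau, water-absorption dips) with genotype-linked
red-edge features, measured in 10 replicate sweeps on the instrument's
native grid (1.4 nm VIS/NIR, 2 nm SWIR), averaged, and interpolated to
one point per nanometer over 350–2500 nm (2151 points). Temperatures are
a seasonal sinusoid with weather noise.

What the generator does not emulate — and hence what passing tests do not
establish about real field data: segregation distortion, residual
heterozygosity, epistasis, spatially structured (non-exchangeable) block
effects, non-Gaussian measurement error, missing-not-at-random
phenotypes, and genetic map error. The within- vs among-genotype variance
split of real data is unknown; defaults were chosen once for realistic
detectability and are not tuned per analysis.

## Problem sizes and numerical choices

Simulation studies in the test suite run scaled-down configurations
chosen as package defaults for desk-scale reproducibility: short MCMC
preset (8,000 iterations), 100–1,000 permutations, 30–100 RILs on 1–5
chromosomes, 2–8 leave-k-out rounds. The full-scale protocol (500k
iterations, 10,000 permutations, 119 RILs, 20 rounds) is available
through the same interfaces as configuration presets.

Numerical details: percentile envelopes use linear-interpolation
percentiles; REML optimizes log-variances by Nelder–Mead from two starts,
clipped to e^±30; scan positions with near-zero dosage variance score
LOD 0; the permutation threshold uses the empirical quantile of
genome-wide maxima; equal-LOD peaks resolve to the lowest chromosome and
position; spectra band windows are inclusive on both endpoints (the
convention is stated because interval notation for bands is often
ambiguous).

## Known limitations

* The LRT for variance components uses the nominal χ²₁ reference despite
  the boundary problem (conservative).
* The hierarchical model assumes lognormal genotype and plant parameter
  variation; strongly skewed architectures (e.g. a single huge QTL) bend
  that assumption, though posterior means remain serviceable point
  estimates for mapping.
* Conditional scans residualize on dosages rather than refitting the full
  mixture likelihood; with dense maps and inbred populations the
  approximation error is negligible, but it is an approximation.
* Named literature vegetation indices ship without formulas; only the
  red:far-red ratio is built in, and other indices must be supplied as
  band-math config entries.
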