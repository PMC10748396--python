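# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions a user should know before trusting
or extending the results.

## Data model

A dataset is three tables. Individual trait records carry species and
community labels plus nine trait columns (LDMC mg g⁻¹, SLA m² kg⁻¹, leaf
C:N, δ¹³C ‰, SDMC mg g⁻¹, Hv cm² cm⁻², SRA m² kg⁻¹, Rdi mm, root C:N);
the trait set is configurable per dataset. Composition is long-format
plot × species canopy cover in metres of line-intercept; totals may exceed
the transect length because canopies overlap, so relative abundance is
always cover divided by the plot's own summed cover. The environment table
holds one row of abiotic descriptors per plot.

Orientation is circular. The models treat it as one continuous predictor,
so the package ships `northness(aspect) = cos(aspect·π/180)` as the
documented encoding and otherwise accepts whatever pre-transformed numeric
column the user supplies; no encoding is guessed.

Dominance filtering (`select_dominant_species`) ranks species by summed
community cover, descending, ties broken by species id, and returns the
shortest prefix reaching the cumulative-share threshold (default 0.90) —
the usual rule deciding which species are measured for traits. Raising
the threshold can only extend the prefix.

## Trait syndromes

PCA runs on the correlation matrix: the traits carry incommensurate units,
and the eigenvalue-greater-than-one retention rule is only meaningful when
every trait contributes unit variance. Retention is strict (> 1, with
eigenvalues within 1e-9 of 1 excluded — an explicit tie policy).
Individual scores are projections of the z-scored rows onto unit-norm
eigenvectors, so score variance per axis equals its eigenvalue and
explained fractions over all axes sum to one.

Missing cells are filled with the species-level mean over all measured
individuals of that species before standardization. This is aimed at
traits measured at a coarser grain than the individual — the Huber value
is typically measured regionally on a few individuals per species — and
it is the finest complete information available. No other imputation is
attempted; a trait missing for an entire species is an error.

Axis signs are deterministic: each axis is oriented so its
largest-magnitude loading is positive, and a per-axis `pin_positive`
override lets users force a named trait positive (e.g. SLA on the leaf
axis so acquisitive strategies score high).

## Community-weighted moments

The estimators are the population (weight-only) forms — no small-sample
bias corrections — and kurtosis is reported as excess kurtosis, so a
Gaussian community scores 0 and the differs-from-zero test reads directly
as a departure-from-normality test for CWS and CWK. These two conventions
are deliberate and stated here prominently because other definitions
(bias-corrected weights, raw kurtosis) shift values by O(1/n) and by 3
respectively.

The per-individual weight is p_s/n_s (species plot abundance divided by
the species' scored-individual count in the plot's community). This is the
unique rule that (a) makes species contribute exactly their cover share
and (b) collapses to the classical species-level community-weighted
moments when conspecific individuals are identical. A species with cover
but no scored individuals raises an error by default; an explicit option
drops it and renormalises, with the drop logged.

Moments are computed per plot (plot abundances weighting community-level
individual scores) and then summarised per community — mean, SD,
SE = SD/√n and a Student-t 95% interval over the community's plots, with
the flag set when the interval excludes zero. Plots are the replicates;
with fewer than two defined values the summary degrades to a sentinel
rather than fabricating an interval. A weight-degenerate plot (zero
weighted variance) reports CWV 0 with CWS/CWK as NaN, not an exception.

## Driver models

All-subsets linear modelling over the abiotic terms plus a community
factor (entering and leaving as one block; treatment contrasts, reference
level = lexicographically first). AICc uses the Gaussian-likelihood
convention with k counting every estimated parameter including the
residual variance: AIC = n ln(RSS/n) + n ln 2π + n + 2k, AICc = AIC +
2k(k+1)/(n−k−1). Ties at the minimum break by fewer parameters, then
lexicographic term order; rank-deficient subsets are skipped with a
warning; subsets with n ≤ k+1 are not fittable and are excluded.

Variance shares are Type-II sums of squares — the RSS increase when the
term (or factor block) is dropped from the best model — expressed as a
percentage of the response's total SS, with the residual share reported
alongside. Without interactions, Type-II equals partial SS; shares plus
residual total 100% only in orthogonal designs, which is the expected
behaviour of this definition. The factor's "slope" is printed as "+"
since a multi-level factor has no single direction.

Community differences use the classical one-way F test and Tukey HSD
pairwise p-values from the studentized-range distribution with N − g
error degrees of freedom (Tukey–Kramer form under unequal group sizes).
Compact letters come from the maximal cliques of the non-significance
graph, so two groups share a letter exactly when their adjusted p ≥ α.
The pairwise stage can be skipped (`tukey=False`) in simulation loops
because the studentized-range tail is expensive to evaluate.

## Turnover/ITV decomposition

The specific series weights species × community mean scores with the focal
plot's abundances; the fixed series weights species means pooled over all
individuals across communities; ITV is their per-plot difference. The same
design — community factor, or the abiotic variables the AICc stage
selected for that axis's CWM — is fitted to all three series. Because the
per-plot identity is linear and the design shared, each stratum satisfies
SS_specific = SS_turnover + SS_itv + SS_cov exactly, with the covariation
term defined as the remainder (twice the cross term). Covariation is
reported signed: a negative value means plots where species replacement
raises the CWM are plots where within-species shifts lower it, and
suppressing that sign would misstate the additivity. Shares are reported
both within each stratum and relative to the total-stratum specific SS.
Both partitions (community factor; selected abiotic variables) are always
run and reported separately.

An axis whose largest-magnitude loading belongs to a regionally measured
trait (by default the Huber value) is refused for decomposition with an
explanatory error: its community-specific species means do not exist by
measurement design, so an ITV component there would be an artifact of
data structure.

## Synthetic generator

The generator emulates a transect study across an ecotone: gradient
positions in [0, 1], six communities on equally spaced segments, ten
plots per community jittered within their segment, Gaussian species cover
responses (optimum, breadth, maximum cover drawn per species; covers below
0.05 m recorded absent; compositions redrawn, at most 100 times, if a plot
comes up empty), and five individuals per species × community.

Traits follow a three-block latent-factor model (leaf economics, root
economics, hydraulics) with fixed loadings and per-trait residual noise.
The two economics latents carry the assembly signal per species s and
community c: alpha·u_s + beta·r_s·(g_c − ḡ_s), where u_s is the species
baseline (turnover), g_c the community position, ḡ_s the mean position of
the communities where s occurs, and r_s a per-species relative slope
(ITV). Because every species contributes equally many individuals in each
community where it occurs, its pooled mean is alpha·u_s exactly, which is
what makes the specific/fixed construction recover the two signals
cleanly. Design choices that matter for estimator behaviour:

- each latent's species × community mean structure is normalized to unit
  spread, so the trait correlation blocks (and hence axis ordering) stay
  comparable across scenarios — shares are scale-invariant, so this does
  not touch the ground truth;
- leaf-side ITV slopes are directional (mean 1, spread 0.25), root-side
  slopes idiosyncratic (zero-mean), and the two baselines uncorrelated;
  correlated alternatives make the leading PCA axis a latent mixture whose
  estimated ITV share is biased upward by up to +0.25;
- the hydraulic block (Hv, δ¹³C, part of SDMC) is insulated from the
  economics latents; Hv is emitted for only three individuals per species
  (the regional-measurement pattern), the rest missing, which exercises
  the species-mean fill;
- when a target ITV share θ is requested, the generator first realizes the
  composition, then solves the quadratic in beta that makes the
  latent-level ITV share of CWM variation exactly θ (θ = 1 instead removes
  the between-species signal). The default scenario uses θ = 0.6, an
  ITV-dominant regime typical of fine-scale gradients. Ground truth
  records the realized shares from the realized means, alongside all
  generating parameters;
- abiotic variables are linear in the gradient plus noise, with plausible
  magnitudes for a mid-elevation forest (altitude 1250–1600 m, northness
  in [−1, 1], soil depth 20–60 cm, declining nitrate and phosphate).

What the generator does *not* emulate: spatial autocorrelation between
neighbouring plots, demographic or successional dynamics, covariance
between abundance and trait values within species, non-linear species
responses, and observation error in cover. Tests passing on this generator
therefore certify the estimators and their calibration under the stated
sampling design, not robustness to those real-data complications.

## Numerical conventions and edge cases

- Least squares uses numpy's SVD-based solver; the normal equations appear
  only in test oracles. Rank checks precede fitting and name the aliased
  terms.
- Weighted-moment inputs must be nonnegative weights summing to 1 within
  1e-9; CWV = 0 yields NaN CWS/CWK flagged as degenerate.
- Kaiser retention is strict with a 1e-9 tie band; eigen-decomposition is
  of the symmetric correlation matrix (`eigh`), eigenvalues sorted
  descending.
- Cover ties in dominance ranking and AICc ties break lexicographically;
  all randomness flows from one integer seed through
  `numpy.random.default_rng`, and the pipeline writes no timestamps into
  numeric outputs, so identical configurations produce byte-identical CSV
  bundles.

## Problem sizes used in the checks

The test suite and the acceptance script run the recovery experiments at
the study design's scale (6 communities × 10 plots, 15 species for the
recovery scenarios, 5 individuals per species × community) with 50–100
replicates per target ITV share (400 for the sub-1% checks at θ = 0,
whose per-replicate Monte-Carlo spread is several percent), 100–200
replicates for the selection calibration at n = 60 with 7–8 candidate
terms, 10⁴ replicates for the ANOVA type-I calibration, and 10⁵-point
samples for the shape-statistic convergence. These sizes put Monte-Carlo
error comfortably below the tolerances they are checked against.

## Known limitations

- The eigenvalue ordering of the second and third axes in the default
  scenario is close enough that individual draws occasionally swap or drop
  the hydraulic axis — as happens with real borderline principal
  components. The pipeline handles both outcomes (Kaiser retention is
  data-driven; the regional-trait refusal guards the decomposition).
- Single-draw ITV-share estimates scatter around the generating target by
  roughly ±10–15 percentage points (PCA mixing and 5-individual species
  means); conclusions should rest on the replicate averages the test
  suite computes, or on confidence measures the user builds on top.
- No mixed-effects or spatial models; plots are treated as independent
  replicates within communities.
- Moment estimators are intentionally uncorrected for small-sample bias;
  comparisons with bias-corrected implementations will differ by O(1/n).
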