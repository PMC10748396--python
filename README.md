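# traitmoments

Functional community assembly analysis from individual-level plant trait
data: trait-syndrome axes, abundance-weighted distribution moments,
environmental-driver selection, and the decomposition of community trait
variation into species turnover and intraspecific trait variability (ITV).

The package is aimed at community ecologists working with the standard
field design of vegetation transect studies: plots nested in communities
along an environmental gradient, species canopy cover from line-intercept
transects, and a handful of individuals measured per species and community
for leaf, stem and root traits.

## What it computes

**Trait syndromes.** Traits with incommensurate units are z-scored and
decomposed by PCA on the correlation matrix. Axes with eigenvalue > 1
(Kaiser criterion) are retained and interpreted as ecological strategy
dimensions — typically a Leaf Economics Spectrum (LES), a Root Economics
Spectrum (RES) and a hydraulic-architecture axis. Every individual gets a
score on each axis.

**Community-weighted moments.** For each plot, each individual of species
*s* receives weight *p*<sub>s</sub>/*n*<sub>s</sub>, where *p*<sub>s</sub>
is the species' relative canopy cover in the plot and *n*<sub>s</sub> its
number of scored individuals in the plot's community. The weighted moments
of the axis-score distribution are

- CWM = Σ *w*<sub>i</sub>*x*<sub>i</sub> — the dominant strategy,
- CWV = Σ *w*<sub>i</sub>(*x*<sub>i</sub> − CWM)² — its spread,
- CWS = Σ *w*<sub>i</sub>(*x*<sub>i</sub> − CWM)³ / CWV<sup>3/2</sup> —
  asymmetry (subordinate species on one flank),
- CWK = Σ *w*<sub>i</sub>(*x*<sub>i</sub> − CWM)⁴ / CWV² − 3 — excess
  kurtosis (0 for Gaussian; negative = even/bimodal strategy mixtures,
  positive = strategy convergence).

Per community, each moment is summarised over plots with a Student-t 95%
confidence interval and flagged when the interval excludes zero; community
differences are tested by one-way ANOVA with Tukey HSD letters.

**Environmental drivers.** Each plot-level moment is regressed on abiotic
predictors (altitude, orientation, slope, soil depth, soil chemistry) plus
a community factor. Every subset of terms is fitted and ranked by AICc
(k counts all parameters including the residual variance); models with
ΔAICc < 2 are reported as equally supported, and the best model's terms
get Type-II sum-of-squares shares of the response total SS plus slope
signs, alongside its adjusted R².

**Turnover vs ITV.** For an axis, the *specific* CWM weights
community-specific species mean scores, the *fixed* CWM weights species
means pooled across communities, and their difference is the ITV
component, so specific = fixed + ITV holds plot by plot. Fitting the same
linear model (community factor, or the AICc-selected abiotic variables) to
all three series splits every SS stratum (explained, residual, total) into
turnover (fixed-series SS), ITV (difference-series SS) and a signed
covariation remainder that makes the partition exactly additive.

**Synthetic ecotone generator.** A seeded generator emulates the full
sampling design (6 communities × 10 plots along a 1-D gradient, Gaussian
species cover responses, 5 individuals per species × community, 9 traits
in three correlated blocks, a regionally measured Huber value with
missing cells) with known ground truth, including a calibrated target ITV
share θ of CWM variation. All tests run against it; no field data are
required.

## Worked example

```python
import traitmoments as tm

scenario = tm.SyntheticScenario(seed=7)          # 6 communities x 10 plots
dataset, truth = tm.generate(scenario)           # 370 individuals, 19 species

scores, _ = tm.build_trait_space(
    dataset.traits, axis_names={1: "LES", 2: "RES", 3: "HyArq"})
print(scores.retained)                # ['LES', 'RES', 'HyArq']
print(scores.eigenvalues.round(2))    # LES 3.29, RES 2.37, HyArq 1.73, rest < 1

moments = tm.plot_moments(scores, dataset.composition)
print(tm.summarize_moments(moments).head())

series = tm.decompose(tm.build_cwm_series(scores, dataset.composition, "LES"))
print(series.pct_of_total.loc["total"].round(1))
# turnover 5.3   itv 63.2   covariation 31.6   total_specific 100.0
```

The three retained axes explain 36.5%, 26.4% and 19.2% of trait variance.
For plot 1 the LES moments are CWM 1.52, CWS −0.13, CWK −0.48, and
community 1's LES CWM of 1.505 ± CI [1.41, 1.60] is flagged as differing
from zero. The decomposition attributes 63.2% of LES CWM variation to ITV
and 5.3% to turnover (this scenario's generating ground truth put the ITV
share at 59.9%; single-draw estimates scatter around the target by roughly
±10–15 points, as the recovery experiments below quantify). All-subsets
AICc selection on the LES CWM keeps altitude, soil depth, total soil N and
the community factor (adjusted R² = 0.991), with the community factor
holding the largest variance share — community identity dominating the
abiotic terms.

A command-line interface wraps the same stages:

```bash
traitmoments generate --seed 7 --outdir data/
traitmoments run --config config.yaml
traitmoments decompose data/ --outdir results/
```

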