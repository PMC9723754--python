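# Methods

This note documents the models implemented in `facet2function`, the
assumptions behind them, the defaults of the synthetic-data generator, and
the numerical choices that a user extending the package should know about.

## The analysis chain

The package operationalizes a multi-facet view of the soil microbial
community. Four facet blocks are measured per soil sample — biomass (total
PLFA biomass, SIR-based active biomass), taxonomic profile (bacteria:fungi
ratio, bacterial and fungal Shannon diversity), functional profile
(carbon-catabolism gene score, functional-gene evenness) and physiological
potential (SIR efficiency and range from a MicroResp CO₂ profile) — plus
basal respiration as the realized function, soil chemistry (TOC, TN, TP,
pH, humidity, with C:N and C:P ratios) and the plot's tree species
richness. The chain is: indices → univariate standardized models of the
richness gradient → facet correlations → stepwise multivariate models of
the functions with variance partitioning → recursive path models with
effect decomposition.

## Facet indices

All diversity quantities use natural logarithms. Pielou evenness of a
vector with a single positive class is the 0/0 limit H/ln S and is defined
as 0; a strictly uniform vector returns exactly 1 (special-cased so the
invariant holds to the bit, not to rounding). Rarefaction subsamples reads
without replacement via a multivariate hypergeometric draw, so the expected
retained count of a taxon is depth × count/total; samples below depth are
dropped with a warning by default (configurable to hard-fail). The
dominance index is implemented as the Simpson concentration Σ pᵢ²; since
downstream analyses use Shannon diversity, this choice is inert for the
pipeline's conclusions.

Two readings exist for the functional-gene scaling ("between 0 and 1" vs
"z-transformation" — mutually inconsistent); both are implemented, min-max
per gene across samples being the default and z-scoring an option. The
choice is recorded in the pipeline configuration. FG evenness is computed
on the raw gene vector and is unaffected.

Active biomass is taken as a measured input column; any conversion from an
O₂-microcompensation signal to biomass units is left to a configurable
multiplier applied at load time, because no universal constant applies.

The two rarefaction depth defaults follow the stated assay depths: 28,897
reads for the bacterial 16S table and 16,542 for the fungal ITS table.

## Standardized effect models

Predictors and responses are centered and divided by **two** sample
standard deviations (n−1 denominator). On that scale a regression
coefficient is comparable across continuous and binary predictors, and a
univariate coefficient equals the Pearson correlation — used as an internal
identity test. Functional-form comparison fits linear, quadratic,
polynomial (cubic by default, to be distinct from quadratic) and
logarithmic shapes on identical observations and keeps the linear form
unless a rival's AIC is at least 4 units lower. AIC within the comparison
is computed from the residual sum of squares as n·ln(RSS/n) + 2k with the
RSS floored at numerical precision — without the floor, an exactly
noiseless linear relation would hand the comparison to a higher-order form
on floating-point residue. Stepwise selection is bidirectional from the
full model (the convention of the major statistical environments), falling
back to forward-from-intercept when the full model is not estimable; ties
are broken by candidate order and the full trace is returned.

## Variance partitioning

For three predictor groups the seven subset models are fitted and their
adjusted R² (Ezekiel: 1 − (1−R²)(n−1)/(n−p−1)) combined by
inclusion–exclusion into unique (a, b, c), pairwise-shared (d, e, f) and
three-way (g) fractions. Fractions may be slightly negative — an artifact
of the adjustment — and are reported as computed so that
a+b+c+d+e+f+g equals the full-model adjusted R² exactly; truncation at
zero is a display option only. A raw-R² mode exists for testing, where the
identities are exact by construction.

## Path models

All variables are observed; the model is y = By + e with Cov(e) = Ψ, one
free coefficient per declared directed edge, free variances for every
variable, and free covariances among exogenous variables plus any declared
`~~` pairs. The implied covariance Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ is fitted to the
sample covariance S by minimizing the ML discrepancy
F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p with a quasi-Newton iteration started
from per-equation least squares. For recursive models with uncorrelated
disturbances that start is the optimum, which doubles as a cross-check; the
general optimizer exists because correlation edges between facet blocks
break pure equation-wise fitting. Disturbance variances are
log-parameterized during optimization so the surface stays well conditioned
even when a variance approaches zero; exactly noiseless systems make S
singular, which is reported as an informative error (the covariance
discrepancy is undefined there — no estimator of this family can fit such
data).

Standard errors come from the numerical Hessian of F_ML at the optimum
(expected-information convention, ACOV = 2/(n−1)·H⁻¹); χ² = (n−1)·F_ML;
RMSEA = √(max(χ²−df, 0)/(df·(n−1))) and 0 when df = 0; CFI uses the
independence baseline Σ_b = diag(S); SRMR is the RMS of the standardized
residual covariances. Fit flags implement RMSEA < 0.10, CFI > 0.9,
SRMR < 0.08. Standardized coefficients are est × SD(source)/SD(target) on
model-implied SDs.

Effect decomposition: direct = standardized edge coefficient; indirect =
sum over all directed paths of length ≥ 2 of coefficient products,
enumerated exhaustively over the DAG and cross-checked against
Σ_{k≥2} Bᵏ = (I−B)⁻¹ − I − B; total = direct + indirect exactly. Group
summaries sum absolute standardized effects, counting a direct path when
its two-sided p < α (default 0.05) and a mediated path when every
constituent edge is individually significant; a mode summing |total|
without significance filtering is also provided, since reported group
figures do not always state which convention they use. Delta-method SEs
for indirect effects are not used for filtering.

## Synthetic-data generator

The generator emulates the study conditions: 52 plots at richness levels
{1, 2, 4, 8, 16, 24} (24 included because the high-richness plots are part
of the analysed gradient), 150 samples allocated to plots approximately
evenly with the remainder randomized — the plot-level allocation of the
real samples is not public, so it is configurable rather than inferred.

Three layers:

1. **Soil chemistry.** Multivariate-normal latents with a configurable
   covariance (default: TOC–TN correlation 0.7, weaker TOC–TP and
   humidity links, slight negative pH associations) mapped affinely onto
   observation scales (TOC 20 ± 5 g/kg, TN 1.6 ± 0.35, TP 0.45 ± 0.10,
   pH 4.8 ± 0.35, humidity 0.30 ± 0.05) and clipped to physical ranges;
   at these scales clipping is vanishingly rare, so the requested
   covariance is preserved.
2. **Latent facets.** Each facet is a linear combination of its structural
   parents on standardized scales plus Gaussian disturbance. The default
   coefficients are the thirteen published standardized path estimates
   (active biomass → respiration 0.590, total/active biomass →
   SIR efficiency 0.209/0.258, FG evenness → SIR efficiency −0.179,
   fungal diversity → respiration 0.128, SIR efficiency/range →
   respiration 0.176/0.213, tree richness → total biomass 0.173 /
   bacterial diversity 0.164 / SIR efficiency 0.152, humidity →
   respiration 0.312 / total biomass −0.234, C:P → SIR range 0.269).
   Disturbances of the seven upstream facets are drawn jointly with the
   reported correlations (total↔active biomass 0.45, Cata↔FG evenness
   0.57, active↔fungal diversity 0.20) plus modest −0.25 defaults for the
   B:F pairs that are described only qualitatively. Disturbance SDs are
   auto-scaled so every facet has ~unit variance, making generating
   coefficients directly comparable to fitted standardized estimates;
   explicit overrides (including 0, the noiseless limit) are honored.
   Tree richness enters as the raw species count standardized by its SD;
   a log option exists behind a flag.
3. **Observations.** ASV counts are Dirichlet-multinomial with the log
   concentration linear in the latent diversity facet (pools of 2000
   bacterial and 800 fungal ASVs; read depths drawn uniformly at
   1.02–1.5× the rarefaction depth so the rarefaction stage is always
   exercised). PLFA markers are lognormal around group shares consistent
   with latent total biomass and B:F (14 markers in six groups, 10% of
   biomass in an unclassified pool). Gene abundances are lognormal with a
   catabolic-gene shift tied to the latent gene score and a per-sample
   spread tied (inversely) to latent FG evenness. The MicroResp matrix
   multiplies an activity level (tied to active biomass), a
   substrate-loading spread tied inversely to latent SIR efficiency, and
   an oxalic-vs-alanine contrast tied to latent SIR range; the two range
   substrates carry no profile loading so the evenness and range channels
   remain separable — without that, the computed indices acquire a
   residual covariance that the path model constrains to zero.
   Respiration is the latent plus additive measurement noise, floored at
   a positive value.

At study scale (n = 150) the recomputed indices track their latents with
Spearman ρ ≈ 0.89–0.99 per facet; the recovery tests use ρ > 0.8 at
n = 400 (calibrated once, not tuned to outcomes).

**What the generator does not emulate:** spatial autocorrelation between
plots, plot-level random effects, litterfall seasonality, sequence-level
artifacts (chimeras, primer bias), compositionality beyond the
multinomial, or measurement drift. Passing tests therefore demonstrate
that the pipeline recovers a known causal structure from realistic-scale
noisy observations — not that the published field estimates are correct.

## Problem sizes and numerical choices

Recovery experiments run at n = 1000 (path models, 3-SE criterion per
coefficient) and n = 5000 (univariate richness effect); the
form-selection experiment uses 200 replicates at n = 150; the rarefaction
expectation check uses 10⁵ draws on a 3-taxon toy. Monte-Carlo tolerances
are set at 3 standard errors of the corresponding estimator. Reports
round to 3 decimals (half-even). The SEM optimizer accepts a solution
when the gradient is small or, on stiff near-degenerate surfaces, when a
probe step along the negative gradient cannot improve the discrepancy.

## Known limitations

- No latent-variable measurement models, robust/bootstrap SEs, or
  multi-group SEM; all variables are observed and disturbances Gaussian.
- No mixed-effects models: samples are treated as independent, as in the
  analysis being replicated, although they nest in plots.
- The Gini-dominance naming is resolved as Simpson concentration; users
  needing the Gini-coefficient variant can supply their own index.
- Variance partitioning is univariate-response only (no RDA/CCA).
- BIOM output requires the optional `biom-format` dependency.
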