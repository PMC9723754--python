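# facet2function

Soil microbial respiration drives the soil carbon balance, yet it is usually
modelled from bulk predictors while the microbial community that actually
respires is measured in fragments — biomass here, amplicon diversity there,
functional genes somewhere else. `facet2function` implements, as a reusable
and fully tested pipeline, an analysis framework that brings those fragments
together: it derives per-sample indices for each *facet* of the soil
microbial community (biomass, taxonomic profile, functional profile,
physiological potential), fits standardized linear effect models of a tree
species-richness gradient on every facet, partitions explained variance in
microbial functions among facet groups, and fits recursive path models that
decompose how tree diversity and soil chemistry propagate through the
community to respiration. A synthetic-data generator emulating a subtropical
tree-diversity experiment (~52 plots, richness 1–24 species, ~150 soil
samples) makes every stage testable end to end without access to field data.

It is written for soil ecologists and microbiome researchers who want to run
this multi-facet analysis on their own measurement tables, or to study its
statistical behaviour under a known ground truth.

## Methods at a glance

- **Facet indices.** Shannon diversity H = −Σ pᵢ ln pᵢ, Pielou evenness
  J = H/ln S and Simpson dominance Σ pᵢ² on ASV tables rarefied without
  replacement (defaults 28,897 reads for bacteria, 16,542 for fungi); total
  microbial biomass and bacteria:fungi ratio from grouped PLFA markers;
  a carbon-catabolism gene score (sum of per-gene abundances scaled to
  [0, 1] across samples) and functional-gene evenness; SIR efficiency
  (Pielou evenness of a 14-substrate MicroResp CO₂ profile) and SIR range
  (CO₂ difference oxalic acid − alanine); soil C:N and C:P.
- **Standardized effect models.** Variables are centered and divided by two
  standard deviations, so a univariate estimate equals the Pearson
  correlation; non-linear alternatives (quadratic, cubic, logarithmic) are
  compared by AIC with the linear form retained unless beaten by ≥ 4 units;
  multivariate models are selected by bidirectional stepwise AIC.
- **Variance partitioning.** Adjusted R² of the seven subset models over
  three predictor groups is decomposed by inclusion–exclusion into unique,
  pairwise-shared and three-way-shared fractions; the fractions sum to the
  full-model adjusted R² exactly.
- **Path models.** Observed-variable recursive SEM fitted by minimizing
  F_ML = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p, with RMSEA/CFI/SRMR fit
  indices (acceptance thresholds RMSEA < 0.10, CFI > 0.9, SRMR < 0.08),
  standardized estimates, direct/indirect/total effect decomposition by
  exhaustive path enumeration (cross-checked against the matrix power
  series Σ_{k≥2} Bᵏ), and group-level sums of absolute standardized effects
  over significant paths.

## Worked example

Effect decomposition over a reported standardized path solution — the
seven-coefficient cascade from microbial facets through physiological
potential to respiration:

```python
from facet2function import structure
from facet2function.sem import (
    StandardizedPaths, decompose_effects, group_effect_summary,
)

paths = StandardizedPaths.from_coefficients(
    structure.cascade_model_text(),
    dict(structure.CASCADE_COEFFICIENTS),
    pvalues={e: 0.001 for e in structure.CASCADE_COEFFICIENTS},
)
dec = decompose_effects(paths)
print(group_effect_summary(dec, targets=["respiration"]).table.round(3))
```

```
           source_group      target  direct  indirect  total
                biomass respiration   0.590     0.082  0.672
      taxonomic_profile respiration   0.128     0.000  0.128
     functional_profile respiration   0.000     0.032  0.032
physiological_potential respiration   0.389     0.000  0.389
```

Biomass dominates: its direct effect on respiration (0.590, the active
biomass path) plus the mediated route through SIR efficiency
((0.209 + 0.258) × 0.176 = 0.082) give a total of 0.672, against 0.128 for
the taxonomic profile, 0.032 (indirect only) for the functional profile and
0.389 for physiological potential.

A full synthetic run at study scale, from raw tables to path models:

```bash
f2f run --config run.yaml     # mode: synthetic, seed: 1, 150 samples
```

writes a report bundle whose `summary.txt` ends with, e.g.:

```
tree-richness effects significant at 0.05: ['bac_div', 'fg_evenness', 'sir_efficiency']
SEM cascade: chi2=0.132 df=1 RMSEA=0.000 CFI=1.000 SRMR=0.004 acceptable=True
SEM drivers: chi2=0.699 df=1 RMSEA=0.000 CFI=1.000 SRMR=0.006 acceptable=True
```

plus TSV/JSON tables for every stage (facet indices, tree-richness effects
with functional-form comparison, facet correlations, stepwise function
models with variance partitioning, path estimates and effect summaries).
The same stages are available individually as `f2f simulate`, `f2f facets`,
`f2f effects`, `f2f varpart` and `f2f sem`.

## Layout

```
src/facet2function/
  simulate.py        synthetic design, soil chemistry, latent facets, observations
  indices.py         facet indices from raw measurement tables
  standardize.py     2-SD rescaling (TwoSDScaler)
  effects.py         standardized OLS, functional forms, stepwise AIC
  varpart.py         adjusted-R² variance partitioning
  sem/               path-model spec, ML fitting, effect decomposition
  pipeline.py        end-to-end orchestration (RunConfig, run_full_analysis)
  cli.py             f2f command-line interface
docs/methods.md      model assumptions, parameter choices, limitations
```
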