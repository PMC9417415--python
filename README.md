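# ecogrowth

Tools for relating bacterial population dynamics to the composition of the
growth environment. The package targets the common experimental design in
environmental microbiology where a defined medium is decomposed into its
pure chemical components (ions, sugars, amino acids), each component is
swept over a log-scale concentration gradient against alternative
background combinations of the others, and a plate reader records OD600
growth curves for every combination. From those curves the package asks:
*which components decide each phase of growth, and why would a cell spread
those decisions over several environmental cues?*

It is written for microbiologists and systems biologists analysing
plate-reader screens of combinatorial media, and ships a synthetic-data
generator with planted ground truth so every stage of the analysis can be
validated end to end without external data.

## What it computes

**Growth parameters.** Each OD600 trace is summarised by three read-off
parameters: the lag time τ (time of the first read starting five
consecutive strictly increasing readings), the maximal growth rate r (the
largest mean of three consecutive log-OD slopes between τ and the OD
maximum, in h⁻¹), and the saturated population size K (mean of the three
reads around the OD maximum). Replicates are averaged with per-parameter
CVs and unreliability flags.

**Medium-space structure.** Component concentrations are rescaled into
[0, 1], embedded by PCA, clustered by k-means on (PC1, PC2), and
correlated with the growth parameters by Spearman rank correlation.

**Decision-making components.** τ, r and K are predicted from the
log10-transformed component concentrations by a model zoo (gradient-boosted
trees, k-NN, feed-forward network, random forest, SVR, multiple linear
regression, stacking ensemble) under fivefold nested cross-validation;
models are compared by one-way ANOVA with Scheffé contrasts, and the
fold-averaged impurity importances of the boosted-tree model rank the
components that decide each parameter. Multimodal parameter distributions
can be split at a Gaussian-KDE trough (bandwidth factor 0.3, 1000-point
equal-probability grid) and the prediction re-run per subset.

**Gradient sensitivity.** For one component and one background, the growth
parameter across the component's gradient is rescaled into the unit square
(x: log concentration over its range; y: parameter over its gradient
maximum) and fitted with a cubic polynomial. The sensitivity

    S = 1 − ∫₀¹ ŷ(u) du

is the area above the fitted curve inside the unit box: S = 0 when the
parameter stays at its maximum everywhere, S → 1 when growth collapses
over most of the gradient. Per-component sensitivities S_τ, S_r, S_K
average S over backgrounds; their sum S_g is the global sensitivity, the
variance of the shares S_p/S_g (V_s), the variance of the raw values, and
the minimum interior angle of a three-axis sensitivity triangle quantify
how evenly a component acts across the growth phases, and power-law tails
of the S distributions are fitted by continuous maximum likelihood.

**Survival simulators.** Lag-logistic dynamics
N(t) = K·N₀ / (N₀ + (K − N₀)e^(−r(t−τ))) on a half-hour grid over 24 h,
with unit-scaled random decision makers: one shared uniform variable
(τ_r = K_r = 1 − r_r) versus three variables, independent or coupled with
observed correlation strengths (0.74, 0.58, 0.17). Survival at threshold
d means N(24) ≥ d; strategies are compared across thresholds and, for
final sizes, by the Mann–Whitney U test.

**Amino-acid usage.** Counts of the 20 amino acids over every annotated
protein of a GenBank record, optionally weighted by per-gene expression as
a copy-number proxy, with branched-chain amino-acid (Ile/Leu/Val)
enrichment against the uniform expectations of 5 % and 15 %.

## Worked example

```bash
python examples/05_survival_simulation.py
```

prints (seeded, hence reproducible):

```
d_r   single  triple_independent
0.00   1.000   1.000
0.20   0.324   0.299
0.40   0.000   0.187
0.60   0.000   0.102
0.80   0.000   0.036
At high extinction thresholds the three independent decision makers keep a
markedly larger fraction of populations alive.

median N(24): triple_correlated=0.139  single=0.068
Mann-Whitney U p-value: 3.56e-55
```

With a single shared decision maker, a fast decision (large r) forces a
small capacity (K = 1 − r), so no population can clear a high extinction
threshold: survival is zero from d_r ≈ 0.4. Three independent decision
makers decouple the phases and keep ~4–19 % of populations alive across
the same thresholds, and even with the empirically observed correlations
among τ, r and K the triple strategy doubles the median final population
size — risk diversification as a growth strategy.

The other examples (`examples/01…06`) walk through parameter extraction,
medium-space embedding, decision-component recovery, gradient sensitivity
and amino-acid usage in the same style. The `ecogrowth` console script
chains the stages (`ecogrowth all --seed 1`), writing per-stage CSV/JSON
artifacts and a manifest with seeds and file hashes.

## Layout

```
src/ecogrowth/      library (synthetic, growth, medium_space, ml,
                    sensitivity, simulate, aa_usage, pipeline, cli)
examples/           one narrative script per capability
tests/              pytest suite with brute-force oracles and
                    planted-structure recovery checks
docs/methods.md     model assumptions, parameter choices, limitations
```
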