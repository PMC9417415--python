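# Methods

This note records the models behind each module, the defaults and why they
were chosen, the numerical decisions taken where the design was genuinely
open, and what validation on synthetic data does and does not establish.

## Growth-curve parameterisation

The three growth parameters are read-off rules applied to the raw OD600
readings; no parametric growth model is fitted.

* **Lag time τ** — the time of the first read `i` such that the next five
  reads each strictly exceed their predecessor. Using the *start* of the
  run is the earliest detection consistent with the rule; the resolution
  equals the sampling interval (0.5 h by default). A curve with no such
  run gets a no-growth sentinel (NaN) and is flagged.
* **Maximal rate r** — log-OD slopes are computed by central differences
  (`numpy.gradient`) over the window from τ to the read achieving the OD
  maximum, and r is the maximum over all means of three consecutive
  slopes. Ties for the maximum resolve to the *last* occurrence so a flat
  curve yields a whole-trace window and r = 0 rather than an empty
  window. Non-positive readings inside the window are excluded with a
  warning. On a pure exponential the estimator is exact.
* **Capacity K** — the mean of three consecutive reads whose window
  contains the global maximum: centred when the maximum is interior, the
  three reads nearest the edge otherwise (the edge rule is our choice;
  any 3-window containing an edge maximum gives the same first/last
  three reads).
* **Replicates** — per-parameter means and CVs (sample SD over mean); a
  parameter is flagged unreliable when its CV exceeds 0.12 — the upper
  end of the replicate variation such assays typically show (CV
  0.05–0.12) — or when any replicate carries the no-growth sentinel.
  Flags propagate: downstream tables drop flagged values. An optional
  constant blank subtraction is available but defaults to 0.

Known limitation: the max-of-three-slopes rule amplifies measurement
noise when OD is near the reading floor, because the largest log-slope of
a logistic curve occurs right after the lag where OD is smallest. This is
a property of the rule, not of the implementation; the quality flags are
how the pipeline copes.

## Synthetic data

The generator emulates the study design, not medium chemistry: its job is
to plant statistical structure that downstream stages must recover.

* **Design** — each component is swept over log-spaced levels (default 6)
  between its range minimum and maximum (default 10⁻³–10, four decades),
  against several background contexts (default 6). Backgrounds sample
  every non-target component uniformly on its log range and set it to
  exactly zero with probability 0.2, since minimal concentrations sit at
  zero by design. All outputs are deterministic under a seed.
* **Responses** — each parameter follows a Hill-type logistic in log10
  concentration of its designated determinant component (midpoint at the
  centre of the log range, width 0.8 decades), plus small seeded
  contributions from every other component (2 % of the amplitude each), so
  the determinant dominates the variance while the map stays non-sparse.
  Baselines/amplitudes default to τ ∈ [2.5, 8.5] h, r ∈ [0.25, 1.25] h⁻¹,
  K ∈ [0.1, 1.0] OD — typical for *E. coli* in defined media. An optional
  coupling mixes the three unit-scaled responses with weights (0.74,
  0.58, 0.17) to induce realistic inter-parameter correlations; off by
  default.
* **Curves and noise** — lag-logistic dynamics (closed form below), plus
  additive Gaussian noise truncated at zero, reported at the instrument
  reading resolution of 0.001 OD. Quantisation is part of the measurement
  model: with continuous noise, the five-consecutive-increase rule fires
  spuriously in flat regions (probability 1/32 per start), whereas real
  plate readers print discrete readings. Defaults (noise SD 0.001 OD,
  inoculum 0.02 OD, 4 replicates) were calibrated once so the replicate
  CVs of the extracted parameters land in the 0.05–0.12 band such assays
  report; median CVs on the default design are (0.069, 0.060, 0.002) for
  (τ, r, K). With `noise_sd=0` the exact closed form is returned.
* **Planted faults** — flat no-growth traces and sensor-clipped curves
  (exact plateaus at a ceiling) are generated on demand for
  quality-filter testing. The curve-level saturation detector looks for
  the maximum repeating exactly in ≥ 4 consecutive reads, which a genuine
  stationary plateau with noise does not produce.

Validation on this generator shows that the pipeline recovers *planted*
structure; it does not show robustness to features the generator omits —
medium chemistry (osmotic effects, speciation), death phases, diauxie,
autocorrelated drift, or plate position effects.

Round-trip accuracy of the extraction rules was established on noiseless
curves over the grid τ ∈ {0, 2, 8} h, r ∈ {0.2, 0.5, 1.5} h⁻¹,
K ∈ {0.2, 1.0} OD (72 h assay so slow growers saturate): τ within one
sampling interval, r within 5 %, K within 2 %, in every cell.

## Medium space

Concentrations are normalised per component by their maximum on the
*linear* scale (the designed minimum is zero, so this is min–max
scaling); log-scale normalisation is available by flag. PCA is
mean-centred, with each axis's sign fixed so the largest-magnitude
loading entry is positive (determinism). K-means uses 10 seeded restarts
and relabels clusters by descending size; k defaults to 4 but is a user
choice — no selection criterion is implied. Correlations are Spearman
throughout.

## Machine-learning attribution

Features are log10 concentrations; zero concentrations map one decade
below the component's smallest positive level (our choice — the
transformation must be defined at the designed zeros). Nested CV is
5×5 with shuffled, seeded folds: the inner grid search sees only outer
training rows, which a leakage-canary test verifies by perturbing test
responses and checking the selection is unchanged. Default grids follow
common practice for each family (boosted trees: learning rate 0.001–0.5,
depth 2–5, 300 estimators; SVR: C/γ/ε over powers of two; k-NN: 1–4
neighbours; MLP: four layer layouts with an iteration cap and seed —
its convergence is inherently stochastic and no acceptance check depends
on it). Tests and the orchestrated pipeline use reduced grids and fewer
estimators; grid and estimator count are arguments, not constants.

Importances are the impurity-based attribute of the boosted-tree model
(the quantity practitioners report for GBDT), normalised per fold and
averaged over five folds. Permutation importance would be less biased for
correlated features but is deliberately not substituted.

Distribution splitting uses a Gaussian KDE with bandwidth factor 0.3
evaluated on a 1000-point equal-probability (quantile) grid; the
threshold is the interior density minimum between the two largest modes.
The quantile grid makes the procedure equivariant under affine rescaling
of the values. Unimodal or degenerate inputs return an explicit
not-separable result. The equal-probability reading of "1000 equal areas"
is our interpretation of an ambiguous recipe; it is documented, tested
for its invariances, and easy to swap.

Scheffé comparison: one-way ANOVA across models on per-fold metrics, then
pairwise contrasts at α = 0.05 with critical value (k−1)·F(α; k−1, N−k).
By construction no pair can be significant when the omnibus F is below
its critical value; zero within-group variance is reported as degenerate.

## Gradient sensitivity

Both axes of a gradient are rescaled to the unit square: x is log10
concentration (zeros one decade below the smallest positive level,
consistent with the ML features) normalised over the gradient range, y is
the parameter over its gradient maximum. A least-squares cubic is fitted
(an interpolating cubic when exactly four levels are present) and
S = 1 − ∫₀¹ ŷ du with the integral taken analytically. Values outside
[0, 1] from polynomial overshoot are clamped with a warning. Gradients
with no growth anywhere (p_max = 0) are undefined and excluded from the
per-component mean; the effective background count is reported.

The balance criteria: V_s is the sample variance (m − 1 = 2) of the
shares S_p/S_g around their mean — which is identically 1/3, making
V_s = 0 exactly when the three sensitivities are equal. Two further
printed criteria, (ΣS_p)/S_g and (ΣS_p − 3S′)/S_g with S′ the mean, are
algebraically constant (1 and 0); they are computed as printed and
flagged degenerate rather than "corrected" into something they do not
say. The third is the sample variance of the raw S values; the fourth is
the minimum interior angle of the triangle whose vertices sit at radii
(S_τ, S_r, S_K) on three coplanar axes 120° apart — the angles depend
only on the radii, so the axis orientation is immaterial (tested by
rotation), and the angle is 60° iff the three values are equal.

Power-law tails are fitted by continuous maximum likelihood
(α = 1 + n / Σ ln(x/x_min)) above a cutoff (sample median by default),
with the Kolmogorov–Smirnov distance to the fitted tail as the goodness
measure. The method is our choice; with 41 components the tails are
short, so exponents are indicative rather than precise.

## Survival simulators

Populations follow N(t) = N₀ for t < τ and the logistic closed form
N(t) = K·N₀ / (N₀ + (K − N₀)e^(−r(t−τ))) afterwards, evaluated on the
0.5 h grid from 0 to 24 h with N₀ = K_max·0.001; the closed form equals
N₀ at the lag boundary and iterating it read by read reproduces it
exactly (semigroup property), which the tests exercise. Decision makers
are unit-scaled variables: τ = 24·τ_r, r = r_r, K = K_max·K_r.

* *single*: r_r ~ U(0,1), τ_r = K_r = 1 − r_r. The shared variable is
  taken to be r_r, the variable the trade-off equations are written in.
* *triple_independent*: three i.i.d. U(0,1).
* *triple_correlated*: τ_r ~ U(0,1); r_r = C_τr(1−τ_r) + (1−C_τr)·I_r;
  K_r = C_τK·τ_r + C_rK(1−r_r) + (1−C_τK−C_rK)·I_K with independent
  uniforms I_r, I_K and defaults (0.74, 0.58, 0.17). The constraint
  C_τK + C_rK ≤ 1 keeps K_r a convex combination, hence inside [0, 1].

Survival at threshold d = K_max·d_r means N(24) ≥ d — ties survive, read
literally. One fixed batch of N(24) values is thresholded across the
whole d_r grid (0 to 1 in steps of 0.05), which is statistically
identical to re-simulating per threshold and guarantees monotone
survival curves. The single-strategy curve is validated against a
deterministic quadrature over the shared uniform; arm comparisons use
two-sided Mann–Whitney U (exact for tiny tie-free samples, asymptotic
otherwise) with independent child seed streams per arm so arms are
uncorrelated yet reproducible. At the top threshold d_r = 1 survival is
identically zero for every strategy (N(24) < K ≤ K_max almost surely), so
strategy comparisons there are degenerate by construction; strict
statistical margins are asserted on interior thresholds.

## Amino-acid usage

All CDS features of a GenBank record are counted (the `translation`
qualifier when present, translation from coordinates otherwise); stop
symbols and non-standard residues (U, X, B, Z, …) are excluded from both
numerator and denominator with a logged tally. Expression weighting
multiplies each gene's residue counts by its level — a per-protein
copy-number proxy — so the weighted denominator is Σ level·length;
weighting by level alone would differ only by per-gene length scaling,
and the level·counts form is the documented choice. Replicate transcript
measurements are averaged per gene upstream. Enrichment is reported
against the uniform references 1/20 (5 %) per amino acid and 3/20 (15 %)
for Ile+Leu+Val.

## Orchestration and problem sizes

The pipeline stages communicate only through declared CSV/JSON artifacts;
a manifest records the seed, per-stage wall time and SHA-256 of every
artifact, and re-running a config reproduces all hashes. Default problem
sizes (8 components × 6 levels × 3 backgrounds; reduced boosted-tree
grids with 100 estimators; 1000 survival simulations per strategy and
10,000 per comparison arm) are chosen so a full run takes seconds on one
core while every statistical conclusion the package demonstrates —
planted-determinant recovery, sensitivity ranking, strategy separation —
is already decisive at that scale. Full-scale runs (41 components, 300
estimators, the complete grids) are a matter of arguments.
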