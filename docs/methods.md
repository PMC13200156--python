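# Methods

## Model

`ndmap` treats the spread of gray-matter pathology as linear diffusion on a
weighted undirected brain graph `G = (V, E)` whose edge weights `w_ij` are
inter-regional connection strengths (e.g. streamline counts from fiber
tractography). With node strength `d_i = Σ_j w_ij`, the symmetric
normalized graph Laplacian is

    H = I − D^{−1/2} W D^{−1/2},

and the pathology load vector obeys the network heat equation
`dx/dt = −βHx` with diffusivity `β`. The closed-form solution

    x(t) = U e^{−Λβt} Uᵀ x₀

is evaluated from the cached eigendecomposition `H = U Λ Uᵀ` rather than by
repeated matrix exponentials: an all-seed scan needs N seeds × T time
points × (1 + n_nulls) networks, and the spectral form reduces each network
to one `eigh` plus cheap matrix products. The two routes agree to machine
precision and this agreement is asserted in the test suite against SciPy's
Padé `expm`.

Consequences of linearity used throughout:

* `x(t; β) = x(βt; 1)` exactly — β and t are degenerate, which is why the
  top epicenter is invariant across a β × horizon grid whenever the horizon
  covers the rescaled peak time;
* each eigenmode's coefficient decays as `e^{−λ_k βt}`, so low-λ modes are
  the persistent spatial patterns, motivating the eigenmode-correlation
  analysis;
* as `t → ∞`, `x(t)` converges to the projection of `x₀` on the zero-mode
  `D^{1/2}·1` (for a connected graph), so late-time predicted patterns are
  degree-driven and carry no seed information.

## Regional contrast

Each region is fit independently by OLS: `volume ~ 1 + group + TIV`. The
group indicator codes controls as 1 ("loss-positive"): a positive
coefficient/t-value means lower volume in cases. The t-map (not the raw
coefficient map) is the default input to the diffusion analysis, with a
`statistic="estimate"` switch. Rectification is `max(t, 0)` for atrophy and
`max(−t, 0)` for expansion, so the two patterns partition `|t|`.

All regions share one design matrix, so the fit is a single QR
factorization. Two numerical choices matter:

* TIV is mean-centered internally (conditioning only; the group coefficient
  is unchanged).
* The residual variance is floored at `(1e−8 × data scale)²`. On exactly
  fitting data (the zero-noise synthetic limit) raw residuals are pure
  rounding error and `t = coef/se` would be rounding-noise ratios; with a
  floor common to all regions the t-map degrades gracefully to a scaled
  copy of the coefficient map, preserving its ranks. Real (noisy) data
  never reaches the floor.

FDR uses Benjamini-Hochberg step-up (the standard meaning of "FDR" in
ROI-level neuroimaging); it is reporting-only — the full rectified map,
not just FDR-significant regions, enters the diffusion analysis. Constant
regions get `t = 0, p = 1` with a warning; a rank-deficient design
(constant TIV or single group) is an error.

## Epicenter mapping

Each region in turn is seeded with unit load; the per-time-point Pearson
correlation between `x(t)` and the observed rectified map (all N regions,
seed included) forms the seed's curve, and seeds are ranked by peak
correlation over the grid `t = 0, 1, …, 50` (unit step matching the
integer horizons used for robustness; no continuous optimization). Ties
break by higher peak r, then earlier peak time, then lower region index —
fully deterministic. Numerically constant predictions (flat late-time
patterns on some surrogate graphs) record r = 0 with a flag rather than
0/0 noise. Pearson is used for the curves and Spearman for the eigenmode
analysis; both are independently configurable, as is excluding the seed
region from the correlation (off by default).

Eigenmode analysis correlates `|u_k|` for the first five modes (ascending
eigenvalue) with the rectified maps; significance is a fixed two-sided
raw-p threshold of 0.01 — acting as the family-wise criterion for a
five-mode family (≈ 0.05/5) — not a separate adjustment procedure.
Cortical-only and subcortical-only correlations are reported when region
tiers are available.

## Degree-preserving null

Surrogate connectomes are built by Maslov-Sneppen double edge swaps on the
binarized topology (preserving every node's binary degree exactly; 10
swaps per edge by default, a common mixing heuristic) followed by a random
permutation of the original weight multiset onto the rewired edges. This is
the nonnegative specialization of signed weighted rewiring, and both
preservation contracts (degree sequence, weight multiset) are asserted
exactly in the tests. A `rewire_fn` hook accepts alternative null
generators.

Per surrogate the statistic is the **maximum peak correlation over all
seeds** (the conservative reading of a "distribution of maximum
correlations"; a candidate-seed-only mode is available). The empirical
value is compared via the null's 95th percentile and the add-one
permutation p `(1 + #{null ≥ emp})/(1 + K)`, which is never exactly zero;
the raw proportion is reported alongside. Occasionally a rewired network
fragments; the Laplacian build then warns instead of failing and diffusion
conserves mass within components, so a long null run is never aborted by
one degenerate surrogate. On pure-noise patterns the add-one p is
empirically super-uniform (verified over 200 replicate patterns in the
acceptance suite).

## Craving correlations

Within cases, Pearson r between the craving score and each region's
volume; Bonferroni `min(1, m·p)` over the tested family, which defaults to
all N regions (the most conservative defensible family; a subcortical-only
family, Spearman, and a TIV-partialled variant are switches). No TIV
adjustment is applied by default.

## Synthetic generator

`SyntheticSpec` defines one study; all randomness derives from a single
seed through named substreams (graph, baseline, tiv, noise, craving), so
fixtures are bitwise reproducible. Defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| n_regions / n_modules | 46 / 4 | modular connectome small enough for thousand-surrogate nulls |
| intra/inter density | 0.6 / 0.02 | dense within-module, sparse bridges; clearly modular, always connected |
| weights | lognormal(0, 0.5), inter-module scaled ×0.3 | heavy-tailed positive weights as in tractography matrices |
| n_cases / n_controls | 288 / 165 | study-scale cohort shape |
| true_seed / plant_time | 7 / 2.0 | the planted effect is `x(plant_time)` from the seed — the forward model itself, so recovery is a genuine inverse problem. `plant_time` sits mid-diffusion: late enough that the pattern has spread beyond the seed, early enough that it has not equilibrated to the degree pattern |
| effect_scale / noise_sd | 400 / 150 (volume units) | "moderate noise": at the 60+40 recovery-benchmark cohort size the observed t-map correlates ≈ 0.93 with the planted pattern, leaving visible estimation noise while keeping the seed identifiable; scaling the effect to ≈ 120 reproduces the harsher ≈ 0.6 regime used for the top-3 recovery property |
| tiv_mean / tiv_sd / tiv_loading | 1.5e6 / 1.5e5 / 0.003 | realistic TIV scale (mm³) contributing ≈ 450-unit between-subject spread — a confound comparable to the observation noise, so the covariate genuinely matters |
| craving_effect | 0.3 | target correlation between case craving scores and the designated (subcortical, by default the last) region's volume; scores are reported on a questionnaire-like 50 ± 10 scale (correlations are affine-invariant) |

What the generator does **not** emulate: spatial autocorrelation of
morphometry noise, hemispheric symmetry of effects, site/scanner batch
structure, non-Gaussian volume distributions, or any coupling between the
connectome and the noise. Passing recovery tests therefore demonstrates
the pipeline's correctness and identifiability under the stated forward
model, not performance guarantees on clinical data.

## Problem sizes in the test and acceptance runs

Recovery benchmarks use 50 replicates at 46 regions with 60 cases + 40
controls; the null-model contracts run 1,000 surrogates at 46 regions and
the super-uniformity check 200 noise patterns × 100 surrogates at 30
regions (reusing one surrogate set across patterns, which leaves the
marginal law of each p-value unchanged); GLM calibration uses 2,000
simulated null regions. These sizes give stable rates (binomial slack is
quoted wherever a rate is asserted) while keeping the full suite fast.

## Known limitations

* The diffusion model is linear and single-seed; epidemic-style or
  nonlinear aggregation dynamics and multi-seed initializations are out of
  scope.
* Connectivity matrices are consumed as given: any thresholding, log
  transform, or density normalization is the caller's responsibility and
  will change H.
* The null preserves degrees but not spatial embedding; spin tests or
  variogram-matched surrogates would be needed to control for spatial
  autocorrelation.
* Model time is in arbitrary units (β = 1 by default); no calendar-time
  interpretation is attached to t.
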