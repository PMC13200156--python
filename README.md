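# ndmap

Network-diffusion mapping of disease epicenters on structural brain
connectomes.

Many neuropsychiatric and neurodegenerative conditions show gray-matter
alterations that are not randomly scattered: they appear to originate in
focal "epicenter" regions and spread along white-matter connections. The
network diffusion model (NDM) formalizes this idea as heat flow on the
structural connectome. `ndmap` implements the full analysis chain needed to
apply it to a case-control morphometry study:

1. **Regional contrast** — per-region GLM `volume ~ group + TIV` across
   subjects (total intracranial volume as nuisance covariate), with
   Benjamini-Hochberg FDR for reporting; the t-map is half-wave rectified
   into an *atrophy* pattern (volume loss in cases) and an *expansion*
   pattern (volume gain).
2. **Diffusion model** — with the symmetric normalized graph Laplacian
   `H = I − D^{−1/2} W D^{−1/2}`, pathology spread obeys the network heat
   equation `dx/dt = −βHx`, solved spectrally as
   `x(t) = U e^{−Λβt} Uᵀ x₀`.
3. **Epicenter mapping** — each of the N regions in turn is used as seed
   (`x₀ = e_s`); the Pearson correlation between `x(t)` and the observed
   rectified pattern is traced over `t = 0…50`, and seeds are ranked by
   peak correlation. Robustness is checked over a β × horizon grid.
4. **Eigenmode analysis** — Spearman correlation of the first five
   Laplacian eigenvector magnitudes with the observed patterns
   (whole-brain, cortical-only, subcortical-only; significance at
   p < 0.01).
5. **Specificity null** — 1,000 degree-preserving rewired connectomes
   (Maslov-Sneppen double edge swaps + weight-multiset permutation); the
   empirical peak correlation is compared against the null's 95th
   percentile and an add-one permutation p-value.
6. **Symptom correlations** — Pearson correlation of a continuous craving
   score with regional volumes within cases, Bonferroni-corrected.

Because raw clinical MRI datasets of this kind are generally not publicly
distributable, the package ships a **synthetic study generator** with a
planted ground truth: a modular weighted connectome, a TIV confound,
Gaussian observation noise, a case-group volume loss planted along the
diffusion pattern from a known seed, and craving scores coupled to
designated subcortical regions at a known correlation. Every stage of the
pipeline is validated by recovering that ground truth.

## Worked example

```python
import numpy as np
from ndmap import (SyntheticSpec, generate_dataset, fit_regional_glm,
                   rectify_contrast, build_laplacian, EpicenterMapper,
                   null_distribution, DiffusionParams)

spec = SyntheticSpec(n_cases=60, n_controls=40, true_seed=7, rng_seed=1)
connectome, cohort = generate_dataset(spec)

contrast = fit_regional_glm(cohort)                  # volume ~ group + TIV
atrophy = rectify_contrast(contrast, "atrophy")      # max(t, 0)

mapper = EpicenterMapper(beta=1.0).fit(build_laplacian(connectome), atrophy)
print("top seed:", mapper.epicenter_,
      "peak r = %.3f at t = %g" % (
          mapper.peak_r_[mapper.epicenter_], mapper.peak_t_[mapper.epicenter_]))

null = null_distribution(connectome, atrophy, DiffusionParams(),
                         candidate_seed=mapper.epicenter_,
                         n_nulls=200, rng_seed=0)
print("null 95th pct = %.3f, empirical p = %.4f"
      % (null.percentile95, null.empirical_p))
```

Output:

```
top seed: 7 peak r = 0.894 at t = 2
null 95th pct = 0.732, empirical p = 0.0050
```

The planted seed (region 7) is recovered as the top-ranked epicenter; its
peak correlation of 0.89 far exceeds the degree-preserving null's 95th
percentile, and the empirical p is the smallest value attainable with 200
surrogates (1/201), i.e. no rewired network matched the real connectome's
fit.

The same analysis runs from the shell:

```bash
ndmap simulate --n-regions 46 --n-cases 60 --n-controls 40 --outdir study/
ndmap epicenter study/connectome.tsv study/labels.csv study/cohort.csv --mode atrophy
ndmap run-all config.yaml     # full pipeline, both directions + null + craving
```

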