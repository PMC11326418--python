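# infantflow

Analysis toolkit for cerebral blood flow (CBF) development in infancy:
quantification of global and regional CBF from phase-contrast and
pseudo-continuous arterial spin labelling (pCASL) MRI, in-scanner
motion QC, developmental trajectory modelling with Akaike-weight model
selection, segmented (breakpoint) regression, orthonormal projective
NMF parcellation into a limbic–sensorimotor–association hierarchy,
permutation-tested spatial map alignment, and penalized-spline GAM
brain–behaviour association.  A synthetic cohort generator reproduces
the statistical structure of an infant perfusion study (ages ~1.4–28
months, logarithmic/biphasic CBF growth, three-cluster regional
hierarchy, Bayley-like behaviour scores) with known ground truth, so
every stage is testable end to end without patient data.

It is written for researchers working with infant perfusion MRI who
want a reproducible, scriptable reference implementation of this
analysis chain, in the style of statsmodels: model objects are built
from data, `fit()` returns results objects carrying estimates,
uncertainties and `summary()` tables.

## The models at the core

**Quantification.**  Global CBF from arterial flux:
`gCBF = 100 Σflux / (ρ V)` with ρ = 1.06 g/mL.  Regional CBF from the
single-compartment pCASL kinetic model:

    rCBF = 6000 λ (ΔM/M₀) e^{PLD/T1a} / (2 α T1a (1 − e^{−τ/T1a}))

(λ = 0.9 ml/g, α = 0.86, T1a = 1.8 s, PLD = 1.8 s, τ = 1.6 s), then
calibrated so the mask mean equals the phase-contrast global CBF.

**Trajectories.**  Five candidate families (linear, logarithmic,
exponential, Poisson, quadratic) are ranked by AIC = −2lnL + 2k through
Akaike weights; the logarithmic model `CBF ~ β ln(age) + covariates` is
applied voxel-wise to produce age-effect Z maps with Bonferroni
thresholds, fitted map stacks over 1–28 months, and rate maps β/age.

**Breakpoints.**  Continuous piecewise-linear fits with 0–3 breakpoints
ψ by Muggeo's iterative linearisation, delta-method CIs, and
extra-sum-of-squares F tests between nested fits.

**Parcellation.**  Orthonormal projective NMF,
`min ‖X − WWᵀX‖²` with `W ≥ 0, WᵀW ≈ I`, hard labels by maximal
weight, and K selected over 2..20 by Davies-Bouldin and
Calinski-Harabasz indices.

## Worked example

```python
import numpy as np
from infantflow import cohort, segmented, trajectory

# a synthetic global cohort (n=119) with a biphasic growth truth
syn = cohort.generate_cohort(
    cohort.GeneratorConfig.global_cohort(trajectory_family="biphasic",
                                         seed=40000))
age = syn.ages
cbf = syn.cohort_table["global_cbf"].to_numpy()

models = trajectory.fit_candidate_models(age, cbf)
print(models.summary().round(3))

fit = segmented.fit_segmented(age, cbf, n_breakpoints=1)
print(fit.summary())
```

prints

```
              loglik  k      AIC      BIC      r    dAIC   wAIC
family
logarithmic -393.376  3  792.753  801.090  0.816   0.000  0.947
quadratic   -395.256  4  798.511  809.628  0.809   5.759  0.053
linear      -411.603  3  829.205  837.543  0.738  36.453  0.000
exponential -417.406  3  840.813  849.150  0.707  48.060  0.000
poisson     -423.544  2  851.088  856.647  0.704  58.336  0.000

Segmented regression: 1 breakpoint(s), n=119, adj R2=0.6920
  psi_1 = 10.97 months (SE 0.76, 95% CI 9.47, 12.47)
  phase 1 slope = 3.190 +/- 0.250 ml/100g/min per month
  phase 2 slope = 0.470 +/- 0.158 ml/100g/min per month
```

The logarithmic family wins the AIC comparison (Akaike weight 0.95 on
this draw — the weight is the probability the family is best among the
candidates), and the one-breakpoint fit places the change from fast to
slow CBF growth at about 11 months, with the first-phase growth rate
(~3.2 ml/100g/min per month) roughly seven times the second-phase rate.

A regional cohort exercises the full pipeline — quantification
round-trips, motion QC, voxel-wise Z maps, per-cluster breakpoints,
opNMF parcellation with K selection, alignment trajectories and the
behaviour GAM:

```python
from infantflow import io
results = io.run_pipeline(cohort.GeneratorConfig(seed=7), out_dir="out")
print(results["k_selection"].chosen_k)        # 3 clusters
print(results["cluster_segmented"]["limbic"].psi)
```

The same stages are exposed on the command line:

```bash
infantflow simulate --n-subjects 76 --seed 7 --out cohort_dir
infantflow qc --motion-file cohort_dir/motion/sub-000_motion.par
infantflow segment --cohort-table cohort_dir/cohort.tsv --breakpoints auto
infantflow parcellate --cohort-dir cohort_dir --k auto
```

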