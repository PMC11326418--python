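# Methods

`infantflow` implements a complete analysis chain for infant cerebral
blood flow (CBF) development — quantification, motion QC, trajectory
modelling, breakpoint detection, parcellation, spatial alignment and
behaviour association — together with a synthetic cohort generator that
provides ground truth for every stage.  This note records the models,
the parameters that matter, and the design decisions taken where the
design was genuinely open.

## CBF quantification

**Global CBF (phase-contrast MRI).**  Global CBF is the summed flow
flux through the four feeding arteries (bilateral internal carotid and
vertebral arteries) divided by brain parenchyma mass:

    gCBF = 100 * (sum of fluxes [ml/min]) / (rho * V_brain [mL])

with tissue density `rho = 1.06 g/mL`.  Units: ml/100g/min.

**Regional CBF (pCASL).**  The single-compartment kinetic model of the
ASL consensus recommendations:

    rCBF = 6000 * lambda * (dM / M0) * exp(PLD / T1a)
           / (2 * alpha * T1a * (1 - exp(-LabelDur / T1a)))

Defaults: partition coefficient `lambda = 0.9 ml/g`, labelling
efficiency `alpha = 0.86`, arterial T1 `T1a = 1.8 s`, post-labelling
delay `PLD = 1.8 s`, labelling duration `LabelDur = 1.6 s`.  All times
are stored in seconds; configuration values quoted in milliseconds must
be converted at the boundary — this keeps the 6000 factor dimensionally
consistent with ml/100g/min.  `dM` is the mean control-minus-label
difference over retained pairs; `M0` is the mean of the acquired pair
of equilibrium-magnetisation images.

**Calibration.**  Labelling efficiency and arterial T1 vary across
infants, so each rCBF map is rescaled by the single scalar that makes
its mask mean equal the phase-contrast global CBF.  Calibration is
idempotent and preserves the spatial pattern exactly.

**Scrubbing and pairing.**  Volumes whose volume-to-volume RMS
displacement exceeds 0.5 mm are removed.  Because an unpaired
control/label subtraction is undefined, scrubbing removes the whole
pair whenever either member is flagged.

**Test-retest ICC.**  ICC(2,1) — two-way random effects, absolute
agreement, single measurement — treating voxels as targets and scans as
repeated measurements, with the F-distribution 95% CI (computed via
pingouin).  This is the standard absolute-agreement choice for
scanner test-retest data.

## Motion metric

Rigid realignment parameters (3 rotations in radians, then 3
translations in mm per volume — the MCFLIRT column order) are condensed
to a per-volume displacement by Jenkinson's RMS formulation: for the
relative transform `M = T_i T_{i-1}^{-1}` with linear part `A = M_3x3 - I`
and translation `t`,

    RMS = sqrt(R^2/5 * tr(A^T A) + t^T t)

over a sphere of radius `R = 50 mm` (configurable).  Pure translations
displace every voxel equally, making that component radius-independent;
pure rotations reproduce the analytic ball-averaged chord RMS
`R * sqrt(4 (1 - cos theta) / 5)`.  The mean relative displacement (MRD)
is the arithmetic mean of the per-volume vector (first entry 0), and is
computed on the full series *before* scrubbing, since it serves as the
per-subject motion covariate.  Volumes above 0.5 mm are scrubbed
(strict inequality: exactly 0.5 mm is retained); subjects with
MRD > 0.5 mm are excluded.

## Developmental trajectory models

Five candidate families are fitted to CBF against age (months):
linear, logarithmic (`y ~ ln(age)`), exponential (`y = a e^{b age}`,
nonlinear least squares with log-linear initialisation), Poisson (GLM
with log link; the log-likelihood is evaluated at the continuous
response through the gamma function, a documented approximation since
CBF is not a count), and quadratic.  All logarithms of age are natural
logarithms; evaluating the default global curve
`16.38 ln(age) + 16.85` with natural log yields physiologically
sensible CBF at both age extremes (~17 at 1 month, ~71 at 28 months).

Models are ranked by `AIC = -2 ln L + 2k`, where `k` counts every
estimated parameter including the residual variance for Gaussian
fits — the convention used by R's `AIC()`, against which the
implementation agrees to four decimals.  Akaike weights are
`exp(-dAIC/2)` normalised to sum to one.

Voxel-wise age effects use vectorised OLS of each voxel's rCBF on
`ln(age)` plus sex and MRD.  The age coefficient's two-tailed t-test p
is mapped through the standard normal quantile and signed by the
coefficient, reproducing the p-to-Z pairing of the Bonferroni threshold
(p = 3.47e-7 at 144,237 tests corresponds to Z = 5.1).  Fitted map
stacks are predicted on the 55-point age grid 1.0–28.0 months in 0.5
steps, fixing head motion at the cohort-average MRD (0.22 mm) and
averaging the sex effect over both sexes (sex = 0.5 under 0/1 coding).
Growth-rate maps are the first derivative of the fitted logarithmic
curves, `beta / age`.

## Segmented (breakpoint) regression

Continuous piecewise-linear models with 0–3 breakpoints are estimated
by iterative linearisation (Muggeo's scheme): regress on `x`, the hinge
`(x - psi)+` and the gap indicator `-1(x > psi)`, update
`psi <- psi + gamma / beta_hinge`, and iterate until the step vanishes.
Numerical choices: starting points at the age quantiles with
multi-start over shifted quantile grids plus a coarse profile scan, a
local fine profile scan (step 0.025) around the solution to guard
against adjacent local basins of the profile residual surface, and a
profile grid-search fallback when the iteration fails outright.  Phases
with fewer than 3 observations invalidate a fit.  Breakpoint standard
errors use the delta method `SE(psi) = SE(gamma)/|beta_hinge|` with t
quantile CIs; estimates and SEs match R's `segmented` package to 3–4
decimals on identical data.  Delta-method intervals are mildly
anticonservative at the default cohort conditions (true coverage of the
nominal 95% CI is about 88% over 400 simulated cohorts); a bootstrap CI
is not provided.  Nested models are compared with extra-sum-of-squares
F tests; the breakpoint count is increased while the F test is
significant and the adjusted R-squared improves.  Covariates, when
supplied, are partialled out of the response by OLS residualisation
before the segmented fit.

## opNMF parcellation

The voxel-by-subject rCBF matrix `X >= 0` is factorised as `X ~ W H`
with `H = W^T X`, minimising `||X - W W^T X||_F^2` under `W >= 0` and
(approximately) orthonormal columns.  The solver is the projective
multiplicative update `W <- W * (X X^T W) / (W W^T X X^T W)`; products
with `X X^T` run through the thin SVD factor `A = U S`, which makes an
iteration O(M N K) instead of O(M^2 K).  During iterations `W` is
renormalised by its spectral norm (the projective-NMF convention, which
in testing reached both lower objective values and cleaner components
than per-column renormalisation); the returned `W` has unit columns.
Initialisation is deterministic NNDSVD (with mean-fill of zeros), so
fits are reproducible without a seed; a seeded random initialisation is
available.  Orthonormality is not enforced exactly — the residual
off-diagonal mass of `W^T W` is reported.  The objective trace is
checked to be non-increasing (a damped half-step is taken when the
multiplicative step overshoots, and the iteration stops if no descent
is possible).  Convergence: relative objective change below 1e-7 or
5000 iterations (1500 during K scans).

Hard labels assign each voxel to its highest-weight component (ties to
the lowest index).  The component count is scanned over K = 2..20; each
hard parcellation is scored with the Davies-Bouldin (lower better) and
Calinski-Harabasz (higher better) indices computed on the voxels'
subject-profile rows of `X` — the matrix the factorisation itself sees.
The chosen K minimises the summed rank of the two indices, with ties
going to the smaller K.

## Spatial alignment statistics

Pearson correlation between two maps over the shared mask, with
significance from a surrogate null built by freely permuting one map's
in-mask values (default 10,000 shuffles).  The test is one-sided
greater, matching the question "does alignment exceed chance"; the
empirical p uses add-one smoothing, `p = (#exceedances + 1)/(n_perm + 1)`,
so the smallest reportable value is 1/10,001 — zero exceedances at
10,000 shuffles reports p < 1e-4.  Free shuffling ignores spatial
autocorrelation; no spin-test style null is provided, a known
limitation.  The alignment trajectory evaluates this correlation for
each map of the fitted age stack against a reference topography (for
instance an adult glucose-metabolism map).

## Behaviour association

Regional CBF is modelled as

    rCBF ~ behaviour + s(age) + sex + motion + SES

where `s(age)` is a penalized cubic B-spline (basis dimension 5 —
a small basis is forced by n = 49 — smoothing weight chosen by
generalized cross-validation via statsmodels' GLMGam).  The t statistic
of the behaviour term is the inferential quantity.  For voxel-wise maps
the smoothing weight is selected once on the mask-mean signal and
reused across voxels, since all voxels share the same age design.
Voxel t maps are thresholded at t > 2.02 (positive tail, matching the
directional hypothesis; two-sided optional) and cleaned with a minimum
extent of 100 contiguous voxels under 26-connectivity (800 mm^3 at 2 mm
isotropic; 6/18-connectivity configurable).  Cluster-level tests on
cluster-mean rCBF use the Bonferroni threshold 0.05/3 = 0.0167 across
the three Bayley domains.  Subjects missing any of score or SES are
dropped listwise.  The river summary tabulates significant voxels per
(domain, parcel), normalising each domain's row to 1.

## The synthetic cohort

The generator emulates the statistical structure the analyses assume,
not MR physics.  Defaults define the study conditions:

- **Demographics.** n = 76 for regional analyses (119 for global-only
  cohorts), ages truncated-normal(12.5, 7.1) on [1.4, 28] months
  (uniform sampling optional), sex 0/1 with no effect, SES ~ N(45, 12)
  clipped to the Hollingshead-like range [8, 66].
- **Global trajectory.** Logarithmic `16.38 ln(age) + 16.85` or
  biphasic with slopes 3.52 / 0.43 ml/100g/min per month and breakpoint
  10.75 months, anchored to the logarithmic curve's value at the break.
  Subject-level residual SD 6.5 ml/100g/min — calibrated by simulation
  so the logarithmic fit at n = 119 reproduces an age-CBF correlation
  of r = 0.823.
- **Regional hierarchy.** A ~2,100-voxel ellipsoidal gray-matter mask
  on a 20x24x20 grid (2 mm voxels) partitioned into three radial shells
  with voxel fractions 0.20/0.35/0.45: a limbic core, a sensorimotor
  middle shell and a frontoparietal association outer shell.  Each
  cluster follows a biphasic trajectory: breakpoints 6.71, 7.69 and
  10.36 months along the limbic-sensorimotor-association hierarchy.
  Phase slopes and levels are the package's own physiological choices
  (the source analyses do not pin them down): sensorimotor cortex most
  perfused (62 ml/100g/min at its break), limbic least (44),
  association intermediate (53) with the steepest late growth; phase-1
  slopes 3.0/3.8/3.3 and phase-2 slopes 0.35/0.50/0.55 bracket the
  global rates.
- **Voxel noise.** The marginal per-voxel residual SD is 10
  ml/100g/min, decomposed into a subject-level global fluctuation
  (SD 6.5, shared by every voxel — so the regional cohort's mask-mean
  CBF scatters exactly like the global cohort's), a subject-by-cluster
  regional fluctuation (SD 4.0, ~8% of mean regional CBF), and an
  independent voxel component absorbing the remainder.  Real perfusion
  varies between subjects mainly through shared physiological state;
  a purely voxel-independent noise model would make the regional
  cohort's global CBF nearly noiseless (SD ~0.4) and is inconsistent
  with the global conditions above.  Optional Gaussian smoothing
  (FWHM in mm) adds spatial autocorrelation for cluster-extent
  experiments; it is off by default.  Values are floored at 0.1 to keep
  rCBF positive.
- **Consistency artifacts.** Per-subject four-artery fluxes invert the
  global-CBF equation exactly (ICA/VA split ~38/38/12/12% with seeded
  jitter; brain volume grows as `350 + 220 ln(age+1)` mL, ~500 mL at 1
  month to ~1090 mL at 28 months).  The pCASL control/label series (10
  pairs, M0 = 1000) inverts the kinetic model exactly at the default
  zero series noise, so quantification round-trips to machine
  precision.  Motion tables are translation random walks whose
  per-step magnitudes realise each subject's target MRD exactly
  (targets truncated-normal(0.22, 0.13) on [0.02, 0.5] mm).
- **Behaviour.** Bayley-like standard scores (mean 100, SD 15) for
  motor/language/cognitive domains, each correlated (r = 0.5 by
  default) with the age-adjusted mean rCBF of one loaded cluster
  (sensorimotor/frontoparietal/limbic respectively); only 49 of 76
  subjects receive scores, mirroring incomplete assessment.
- **Reproducibility.** One seed; independent child streams per
  component (demographics, maps, fluxes, ASL, behaviour) so enabling or
  disabling one component never changes another's draws.  Identical
  seeds give identical cohorts.

What passing tests on this cohort do *not* show: robustness to spatial
noise structure, partial-volume effects, registration error,
head-size growth or acquisition artifacts — none of which the
generator models.

## Known limitations and honest negatives

- **Model-selection weight.** Over the ages the cohort actually
  samples, a quadratic approximates the logarithmic curve closely, so
  even at the calibrated noise the logarithmic family's median Akaike
  weight on synthetic cohorts is ~0.94, and it exceeds 0.99 in only
  about a quarter of replicates.  Near-certain (>0.99) selection of the
  logarithmic family is a property of real data; the synthetic
  conditions cannot reproduce it, and the corresponding acceptance
  check fails honestly rather than being tuned.
- **Component-count selection.** The modal K over replicate cohorts is
  3 (the ground truth), but the per-replicate rate is about 85%: the
  subject-by-cluster regional fluctuations occasionally pull two
  clusters close together, the two-cluster merge then scores best on
  Davies-Bouldin, and the tie-to-smaller-K rank-sum rule picks K = 2.
  Near-certain per-replicate selection would require either stronger
  cluster contrast or spatially structured noise than the generator's
  defaults provide.
- **Breakpoint CIs** undercover mildly (~88% rather than 95%); the
  implementation matches the canonical R implementation, so this is a
  property of the delta-method interval at these conditions.
- **Permutation nulls** ignore spatial autocorrelation (free
  shuffling), as does the generator's default noise.
- The Poisson family's continuous-response log-likelihood is an
  approximation retained only so the family can participate in AIC
  ranking.

## Problem sizes

Simulation-based checks run at the cohort sizes the analyses define
(n = 119 global, n = 76 regional, ~2,100 masked voxels), with 50
replicates for the global recovery experiments, 50 for the cluster
breakpoints and 20 for the K-selection scan in the acceptance script;
the test suite uses smaller replicate counts of the same experiments.
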