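# Methods

## The scientific problem

Cerebral small vessel disease (cSVD) damages the brain's microvasculature.
The neurovascular unit (NVU) — endothelium, pericytes, astrocytes, neurons
and the perivascular space — regulates cerebral blood flow, blood-brain
barrier (BBB) integrity and perivascular clearance, and its dysfunction is a
candidate common pathway from microvascular pathology to cognitive decline.
Quantitative MRI yields one proxy per NVU function: BBB leakage rate `Ki`
and leakage volume `V_L` from DCE-MRI (BBB integrity), perfusion volume
fraction `f` and microvascular diffusivity `D*` from IVIM (blood-flow
regulation), and the intermediate volume fraction `f_int` from IVIM
(interstitial/perivascular fluid, a clearance proxy). Rather than testing
each marker against each cognitive score, the analysis treats the five NVU
measures and the thirteen neuropsychological test scores as two multivariable
sets and asks how the latent combinations of one set correlate with latent
combinations of the other — canonical correlation analysis (CCA).

## Canonical correlation analysis

Given standardized matrices `X (n×p)` and `Y (n×q)`, CCA finds weight
vectors maximising `corr(Xa, Yb)` subject to orthogonality with earlier
modes, producing `K = min(p, q)` mode pairs. The solver forms the sample
correlation matrices `Sxx, Syy, Sxy` (denominator `n−1`), whitens through
symmetric inverse square roots computed by eigendecomposition with an
eigenvalue floor of `1e-10`, and takes the SVD

    Sxx^{-1/2} Sxy Syy^{-1/2} = A diag(r) Bᵀ.

The singular values are the canonical correlations; weights are the
back-transformed singular vectors, variates are rescaled to exactly unit
sample variance, and loadings are the Pearson correlations between each
variable and its set's variate. Signs are fixed per mode so the X variable
with the largest absolute loading is positive — a pure reporting convention;
the underlying subspaces are sign-indifferent.

Interpretation quantities: shared variance `r_k²`; variance extracted
`VE_k = mean_j L_{jk}²` (how much of its own set a variate captures); the
Stewart–Love redundancy `Rd_k = VE_k · r_k²` (how much of one set's variance
is explainable *through the other set* via mode k), summed over modes for
total redundancy. The mean-squared-loadings form is used because it
satisfies the exact identity `Rd = VE × r²` that links the three reported
quantities. An optional ridge epsilon can be added to a near-singular
within-set correlation matrix; its application is logged.

Degenerate inputs are rejected rather than silently repaired: zero-variance
columns, missing entries, and `n ≤ max(p, q)` raise errors.

## Permutation inference

Mode significance uses the residual Wilks' lambda
`Λ_k = Π_{i≥k} (1 − r_i²)`. Rows of `Y` are permuted uniformly at random
(`X` fixed — an arbitrary but fixed convention; the null is the same either
way), the CCA is refit, and `p_k = (1 + #{Λ_k^perm ≤ Λ_k^obs}) / (1 + B)`
with `B = 1000` by default. The add-one estimator keeps p-values strictly
positive. Because a row permutation leaves the within-set covariances
untouched, both sets are whitened once and each replicate reduces to the
singular values of the cross-correlation of the pre-whitened matrices —
algebraically identical to a full refit and roughly two orders of magnitude
faster, which is what makes the calibration and power simulations in the
test suite cheap.

**Known limitation.** All modes are evaluated against the same full-null
replicate set ("simultaneous" scheme). When a genuine first mode exists,
the observed `r_2` behaves like the *largest* correlation of the residual
structure while the permutation null supplies the distribution of the
*second-largest* of a full null, so p-values for modes `k ≥ 2` are
anti-conservative. First-mode inference — the quantity of scientific
interest here — is correctly calibrated (verified by simulation in the test
suite: type-I error within [0.02, 0.09] at α = 0.05). The `step_down`
scheme enforces monotone non-decreasing p-values across modes but does not
recalibrate higher modes; properly conditioned sequential inference (e.g.
refitting after projecting out earlier variates) is out of scope.

## Score preparation

- Interference scores: TMT `B − A`; Stroop `part3 − (part1 + part2)/2`.
- Inversion: timed tests where higher = worse (TMT interference, Stroop
  interference, TMT A, Stroop I, Stroop II) are negated before analysis, so
  every column reads "higher = better". Negation commutes with z-scoring
  and leaves canonical correlations unchanged.
- Z-scores are sample-based, with the `n−1` denominator. Canonical
  correlations are scale-invariant, so the denominator convention cannot
  affect them; it is fixed for reproducibility of loadings.
- The cognitive battery is **thirteen** tests in three domains: memory
  (RAVLT immediate recall, delayed recall, delayed recognition), executive
  function (TMT interference, Stroop interference, category fluency, letter
  fluency, letter-number sequencing, digit span backward), psychomotor speed
  (TMT A, Stroop I, Stroop II, symbol substitution). Forward digit span —
  primarily an attention/span task — is not part of the battery; this keeps
  the battery at thirteen while retaining every timed component needed for
  the inversion rule.
- Domain compounds average the z-scores within a domain; one missing test is
  tolerated (mean of the rest), more than one renders the compound undefined
  for that subject.
- Covariate adjustment regresses each analysis variable on an intercept plus
  the covariate set (OLS via statsmodels) and keeps the residuals; the three
  shipped sets are none, {age, sex, education}, and additionally relative
  brain and WMH volume. Residualization makes the canonical correlations
  exactly invariant to adding any linear function of the covariates to any
  variable.
- Missing data entering CCA: listwise deletion by default, with the
  effective n reported next to every result; per-variable mean imputation is
  available (`missing="mean_impute"`) as a sensitivity option.

## MRI estimators

**Patlak.** With tissue curve `Ct(t)` and vascular input `Cp(t)`, ordinary
least squares of `Ct/Cp` on `(∫₀ᵗ Cp dτ)/Cp` (trapezoid rule) gives slope
`Ki` and intercept `vp`. The fit window should start after bolus arrival
(quasi-equilibrium assumption); the default simulation uses 25 min sampled
every 12 s and a window starting at sample 10 (t = 2 min). `Cp` must exceed
`1e-12` throughout the window. On noiseless model-generated curves the
estimator is exact because simulation and fit share the same quadrature;
under additive Gaussian noise it is unbiased (noise enters only the
response), verified by simulation.

**Leakage volume.** Negative Patlak slopes can only be noise; mirroring
them about zero yields a symmetric noise sample whose 0.95 quantile is the
detection threshold, and `V_L` is the fraction of voxels above it. The rule
is invariant to positive rescaling of all `Ki`. The 0.95 quantile implies a
~5% false-positive rate on pure noise — the tested property. With no
negative voxels at all the behaviour is explicit: an error by default, or
`threshold = 0` when requested. The exact threshold convention of the
original histogram method is not public; this mirrored-noise quantile is
this package's stated construction.

**Three-component IVIM.** The triexponential model is fitted by
trust-region-reflective least squares inside non-overlapping parameter
boxes — `D* ∈ [5e-3, 1]`, `D_int ∈ [1.5e-3, 5e-3]`,
`D_par ∈ [1e-4, 1.5e-3]` mm²/s, `f ∈ [0, 0.3]`, `f_int ∈ [0, 0.5]` — which
enforce the compartment ordering by construction. Ten starts (box midpoint
plus a seeded Latin hypercube) guard against local minima; the best-RSS
solution is returned and a `converged` flag records whether any start
succeeded. The signal is normalised by the measured b=0 amplitude before
fitting and `S0` rescaled afterwards. The model equations are the scientific
content; the fitter is deliberately a plain deterministic optimiser, and the
test suite checks it against a dense grid-search oracle. Inversion-recovery
CSF suppression is assumed already effective (signals are CSF-free).

## The cohort simulator

The generator's defaults *are* the reference study conditions: 80 recruited
subjects, 7 artefact-flagged exclusions, planted canonical correlations
`rho = (0.73, 0, 0, 0, 0)`, marginal means/SDs from the reference cohort
table (NAWM or WMH variants), and sporadic completely-at-random missing
cognitive tests (rate 0.01 ≈ one missing score per ~8 subjects, matching
"occasional missing tests").

Construction: with loading matrices `Lx (p×K)`, `Ly (q×K)` and residual
SDs, the within-set covariances are `Sxx = LxLxᵀ + diag(σx²)` (likewise
`Syy`); the whitened loadings are orthonormalised to `Qx, Qy` (polar
factor) and the cross-covariance is set to
`Sxy = Sxx^{1/2} Qx diag(rho) Qy^ᵀ Syy^{1/2}`, which makes the population
canonical correlations equal `rho` *exactly*, whatever the loadings.
Subjects are jointly Gaussian draws rescaled column-wise to the marginal
moments (a diagonal transform, invisible to CCA). Timed tests are generated
on their natural raw orientation; preparation's sign flips do not change
canonical correlations.

Default factor structure: one common NVU factor with equal loadings
`c = √0.05` on all five measures — chosen because with unit variances the
population variance extracted by the first NVU variate is `(1 + 4c²)/5`,
i.e. exactly 24.0%; and for cognition a general factor (loading 0.42086,
solved numerically so the first cognition variate's population variance
extracted is 23.1%) plus three independent domain factors (loading 0.35)
that induce realistic within-domain correlation without cross-set
correlation. The within-battery correlation structure of the real tests is
unknown; "general + domain factors with independent noise" is the standard
psychometric stand-in, and its choice affects only the higher (null) modes.
Covariates are drawn independently of the planted structure, so covariate
adjustment is a no-op in expectation — the robustness behaviour the
pipeline's adjusted presets are meant to exhibit.

The ground-truth sidecar stores the planted correlations, the *population*
canonical loadings implied by the construction, and per-subject natural-unit
MRI parameters consistent with the cohort columns (plus fixed `vp = 0.01`,
`D_int = 2.5e-3`, `D_par = 0.7e-3` mm²/s).

What the simulator does **not** emulate: non-Gaussian marginals (real
reaction-time distributions are skewed), floor/ceiling effects in test
scores, informative missingness, measurement-error correlation between NVU
measures sharing an acquisition, and any image-level artefact structure
behind the exclusion flags. Passing recovery tests therefore demonstrates
correctness of the estimators and inference under the stated generative
model, not robustness to those real-data features.

## Numerical and design choices

- Eigenvalue floor `1e-10` in all whitening; covariance denominator `n−1`
  throughout.
- DCE vascular input: saturating-exponential rise (0.15 min time constant,
  arrival 0.5 min) times biexponential washout (fast 1.5 min⁻¹ / slow
  0.03 min⁻¹, 60/40 split), peak ≈ 4 mM at t ≈ 0.9 min. Any smooth positive `Cp` preserves
  Patlak validity; the shape is configurable.
- IVIM noise is additive Gaussian by default (valid in the high-SNR ROI
  regime); Rician magnitude noise is available as an option.
- Problem sizes in the test suite (e.g. 500 cohorts at n = 73, 200 null
  datasets at B = 200, 100 power seeds at B = 1000, n = 5000 for
  planted-correlation recovery) were chosen so each check's Monte-Carlo
  error is small relative to the asserted tolerance while the whole suite
  stays fast enough for routine use.
- Reports are JSON with sorted keys and no timestamps: identical config and
  seed reproduce byte-identical output.

## Known limitations

- Higher-mode permutation p-values are anti-conservative under a strong
  first mode (see above).
- Listwise deletion shrinks n below the post-exclusion count when tests are
  missing; the effective n is always reported, but small-sample optimism of
  `r₁` grows accordingly.
- No regularized/sparse/kernel CCA and no cross-validated canonical
  correlations; with p + q = 18 at n ≈ 70, fitted correlations carry
  substantial optimism and should be read jointly with the permutation test.
- The Patlak model ignores efflux and plasma-tissue water exchange; the
  histogram threshold is a stated substitute for the original method's
  unpublished rule; IVIM compartment boxes encode the three-compartment
  separation as a hard prior.
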