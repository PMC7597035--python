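# Methods

## Model and fitting

All continuous-response fits are ordinary least squares on the
trigonometric design [1, sin(2πit/P), cos(2πit/P)]ᵢ₌₁..ₙ, coefficient order
[M, A₁,₁, A₁,₂, …]. With the period fixed the model is linear, so nested
fits can only lower the SSR and the classical F machinery applies. Count
responses use maximum likelihood on the same design with a log link;
Poisson, generalized Poisson (GP-1: mean μ, variance μ(1+αμ)², covering
under- and over-dispersion) and negative binomial (NB2: variance μ+αμ²)
are delegated to `statsmodels` discrete models. Model significance is the
overall regression F-test for Gaussian fits and a likelihood-ratio
chi-square against the intercept-only model (df = 2N) for count fits,
since the Gaussian F does not apply there.

## Rhythm parameters

Single-component amplitude and acrophase come from the closed forms
A = √(A₁²+A₂²), φ = atan2(−A₁, A₂) wrapped into (−2π, 0]; the atan2 form is
algebraically identical to the four-quadrant arctan case table and is what
the property tests check against a brute-force curve argmax. Acrophase 0
means a peak at time 0; conversion to hours is −φ·P/(2π).

Multi-component parameters cannot be written in closed form, so they are
evaluated from the fitted curve on a grid of P/1000 points over one period
(phase quantisation ≤ 0.36° at P = 24 h; grids coarser than P/4 are
rejected). For asymmetric curves the curve midline (max+min)/2 and the
intercept M genuinely differ; both are reported, as `mesor` and
`mesor_intercept` respectively.

## Test battery

- **Zero-amplitude test**: F = (model SS/2)/(SSR/(n−3)), df (2, n−3).
  Degenerate inputs are resolved by convention: a flat noiseless series
  gives p = 1 (no rhythmic variation), a perfect rhythmic fit gives p = 0
  with an explanatory note.
- **Lack of fit**: SSR is split into pure error (within replicated time
  points) and lack of fit; F = (SS_lof/(c−p))/(SS_pure/(n−c)). Requires
  replicates and more distinct time points than parameters; zero pure
  error with a perfect fit is reported as not applicable rather than as a
  p-value.
- **Extra sum-of-squares**: F = ((SSR₁−SSR₂)/SSR₂)/((DoF₁−DoF₂)/DoF₂) with
  p from F(DoF₁−DoF₂, DoF₂), implemented exactly in this form. Selection
  steps through adjacent component counts (1→2→3…), keeping the richer
  model while p < α (default 0.05); comparing only adjacent counts is a
  deliberate choice — it keeps each step a valid nested test. Among
  per-period winners the smallest SSR wins, with near-ties (relative 1e-9)
  resolved toward fewer components, then the shorter period (parsimony).
- **Period scan**: normalized Lomb–Scargle power on a linear period grid
  (or an explicit candidate list); with ~2 observed cycles the spectral
  peak is intrinsically wide, see Limitations.
- **FDR**: Benjamini–Hochberg step-up via `statsmodels`, validated in the
  tests against the brute-force min-over-tail definition.

## Confidence intervals and sample size

The MESOR gets a t-interval from its OLS standard error. For (A, φ) the
primary intervals project the joint elliptical confidence region of
(A₁, A₂) — boundary (β−β̂)ᵀΣ⁻¹(β−β̂) = 2F₂,df(level), sampled at 720
boundary angles — onto the polar coordinates; this is conservative but
respects the geometry (when the region covers the origin the amplitude
interval starts at 0 and the acrophase is flagged as the full circle).
Delta-method intervals are reported alongside so the projection's extra
width is visible. Empirical coverage of both is exercised in the tests.

Sample-size estimation assumes balanced sampling over whole periods, under
which SE(A) ≈ σ√(2/n) and SE(φ) ≈ σ√(2/n)/A at design amplitude A; the
smallest n (floor 5) whose predicted two-sided t-interval meets the target
length is returned. The 1/√n law means halving a target roughly quadruples
n. Acrophase targets are infeasible at zero design amplitude and raise.

## Population-mean cosinor

Each of k ≥ 3 individuals is fitted separately; population coefficients
are arithmetic means of individual (M, A₁, A₂). Amplitude and acrophase
always derive from the mean coefficient vector, never from averaging
angles or amplitudes directly — vector averaging avoids circular-mean
artefacts and correctly shrinks the population amplitude under phase
dispersion (a property the tests assert). The zero-amplitude test is the
Hotelling-type F: T² = k·m̄ᵀS⁻¹m̄ on the among-individual covariance S of
(A₁, A₂), F = (k−2)/(2(k−1))·T², df (2, k−2). Perfectly concordant
individuals make S singular; that is reported as p = 0 with a note (or
p = 1 when there is also no rhythm). Multi-component population fits reuse
the linearity of the model (mean of curves = curve of mean coefficients),
test each rhythmic coefficient across individuals with one-sample t-tests,
and carry the fundamental-pair Hotelling test as the model-level
zero-amplitude statistic.

## Differential rhythmicity

The joint single-component model adds a group indicator g (0/1):
group a parameters are (A₁ₐ, A₂ₐ, Mₐ) and group b's are the sums
(A₁ₐ+A₁ᵦ, …). Amplitude-change and acrophase-shift standard errors come
from the delta method on the full 6×6 coefficient covariance; p-values are
two-sided t-based Wald tests. Acrophase differences are wrapped into
(−π, π], so phases 0 and 2π−ε differ by ε, not 2π−ε. A single pooled error
term is assumed, as in the model statement; a caveat is attached when the
two groups' residual variances differ by more than 4×.

The joint multi-component route (4N+2 coefficients) only yields a verdict:
any group-b rhythmic coefficient significantly non-zero ⇒ differential
rhythmicity. Because "any of 2N" inflates type I error, the 2N interaction
p-values are Holm-adjusted within the model before the verdict — a
deliberate strengthening documented here.

The nonlinear route fits y = (Aₐ+Aᵦg)·cos(2πt/P − (φₐ+φᵦg)) + Mₐ+Mᵦg by
Levenberg–Marquardt, warm-started from the linear joint fit with up to 5
seeded jittered restarts (the phase parameters make the loss multimodal);
standard errors are asymptotic from the Jacobian. Its contrasts agree with
the linear route within sampling error — it adds direct parameterisation,
not information.

Population comparison uses Welch two-sample t-tests on individual-level
summaries: amplitudes, MESORs, and acrophase deviations wrapped around
each group's vector-mean phase.

Batch comparisons BH-adjust amplitude p-values together and acrophase
p-values together, across pairs.

## Synthetic generator

The generator emulates multi-harmonic rhythms:
y(t) = M + Σ aᵢ·cos(2πit/P + iφ) + e(t), the fundamental acrophase φ
entering harmonic i as iφ so that φ acts as a rigid time shift (φ = π
delays any waveform by half a period). Defaults follow the benchmark
conditions: period 24 h, span 48 h sampled inclusively at both ends,
noise amplitude 0.5, 3 replicates. The benchmark table does not fix
harmonic amplitudes or the MESOR; the defaults are amplitude 1/i for
harmonic i and MESOR 0, which give the 3-component scenarios a multi-peak
profile a single harmonic cannot fit — both are overridable. The noise law
is zero-mean Gaussian with σ = noise amplitude (the cosinor error model);
uniform noise on ±amplitude is exposed as an option. Per-group RNG
substreams are spawned from one master seed, so regeneration is exact and
group draws are independent. A Poisson count generator exponentiates the
cosinor curve as the intensity, matching the log-link GLMs.

What the generator does **not** emulate: damping, trends, period drift,
autocorrelated or heteroscedastic noise, missing data, or realistic
assay-specific error distributions. Passing tests therefore demonstrate
correctness of the statistical machinery under its own assumptions, not
robustness to every failure mode of real recordings.

## Problem sizes and numerical choices

The test suite runs its calibration checks at 400–1000 simulations per
test and the benchmark-pattern checks over 100 generator seeds; the
acceptance script aggregates 25 regenerated replicates per quantity
(medians for q-values and the scanned period, modes for discrete
outcomes). These sizes make the whole suite complete in well under a
minute while keeping Monte-Carlo error small relative to the asserted
bounds. Ties in the curve-parameter grid resolve to the earliest grid
point; SSR comparisons treat values within relative 1e-9 as tied; perfect
fits (SSR ≈ 0 relative to the data scale) short-circuit F-statistics to
p = 0 with an explicit flag rather than dividing by zero.

## Known limitations

- **Period precision is information-limited.** For the 1-harmonic
  benchmark scenario (amplitude 1, σ = 0.5, 75 points over two 24 h
  cycles) the Cramér–Rao bound puts the SD of any period estimate near
  0.54 h (empirically ~0.64 h for the least-squares scan), so a single
  dataset of this size identifies the period only to roughly ±1 h; the
  corresponding acceptance check in `tests/test_acceptance.py` states a
  stricter rate than this bound allows and fails honestly. Longer spans,
  not denser sampling within the same span, are what sharpen the period.
- Fixed-period fits have no period uncertainty of their own; a
  profile-SSR interval over a period grid can be formed from
  `select_best_model` traces but is an interpretation, not a classical
  procedure.
- No mixed-effects population model, no autoregressive errors, no
  non-parametric detection; outlier screening (per-group MAD robust
  z-score, default threshold 5, off by default) is a pre-processing
  convenience, not a calibrated test.
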