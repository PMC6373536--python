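# Methods

## The decision model

Each trial is modelled as a Wiener diffusion process
`dX = v dt + s dW` starting at `z = a/2` between absorbing boundaries at
0 and `a`. The upper boundary is the required response, so positive drift
`v` favours a correct decision; the observed RT is the first-passage time
plus a non-decision offset `Ter` covering encoding and motor execution.
The starting point is always symmetric (`z = a/2`): there is no prior
response bias, and errors arise only from diffusion noise carrying the
process to the wrong boundary. Inter-trial variability parameters of the
full Ratcliff model (`sv`, `sz`, `st0`) are out of scope.

The scaling constant is `s = 1`. Conventions with `s = 0.1` exist and
differ only by a relabelling of units: estimating with scaling `s'`
multiplies `v` and `a` by `s'/s` and leaves `Ter` unchanged (a tested
equivariance). Drift magnitudes around 2 in this package's defaults are
meaningful under `s = 1`. The scaling is threaded explicitly through the
estimator and never hard-coded.

### EZ closed forms

With `y = exp(-v a / s²)`:

- `Pc = 1 / (1 + y)`
- `MDT = (a / 2v) · (1 − y) / (1 + y)`, `MRT = Ter + MDT`
- `VRT = (a s² / 2 v³) · (2 w e^w − e^{2w} + 1) / (e^w + 1)²` with
  `w = −v a / s²`

The inverse is exact: `L = logit(Pc)`,
`v = sign(Pc − ½) · s · [L (L Pc² − L Pc + Pc − ½) / VRT]^{1/4}`,
`a = s² L / v`, `Ter = MRT − MDT`. Round-trip identity holds to better
than 1e−10 over the tested grid. Because the start is symmetric, the
correct- and error-RT distributions coincide, so moments of correct RTs
alone identify the parameters.

Cells with observed `Pc ∈ {0, ½, 1}` are uninvertible; they are nudged by
the minimal-perturbation convention `1/(2n)` (`edge_correct`) and flagged.
Negative `Ter` estimates (possible in small noisy cells) are retained and
flagged rather than clamped — clamping would bias downstream ANOVAs.
Cells that remain uninvertible (fewer than two correct trials) propagate
as flagged NaN records, never silent drops.

## First-passage sampling

Trials are simulated by Euler–Maruyama with step `dt = 0.0005 s` plus a
Brownian-bridge within-step crossing correction: after a step that stays
inside `(0, a)`, the path is additionally absorbed with the exact bridge
probability `exp(−2 (a − x_t)(a − x_{t+dt}) / (s² dt))` of an unobserved
upper-boundary touch (mirrored for the lower boundary). Plain Euler has an
O(√dt) boundary-overshoot bias in hitting probability that is comparable
to Monte-Carlo error at n = 50,000; the bridge correction reduces the bias
to O(dt), which is negligible here. Calibration against the closed-form
hitting probability `1/(1 + exp(−v a/s²))` and the EZ moments is part of
the test suite (3 Monte-Carlo SEs at n = 50,000). Absorption times are
recorded at the end of the step in which absorption occurred, an O(dt)
upward bias on decision time that is far below every tolerance used.

## The synthetic scenario

The default scenario emulates the study conditions the pipeline is meant
to analyse: 32 participants per gender, 16 practice + 256 main trials
each, and a ground-truth parameter table over the 16
gender × expression × response × face-gender conditions.

- **Female drift rates** carry the approach–avoidance pattern at the
  published condition means: angry/push 2.16, angry/pull 1.85, happy/pull
  2.31, happy/push 2.12 (same for both face genders). **Male drift rates**
  carry only a happy (2.15) > angry (1.95) difference, with no response
  effect.
- **Female non-decision times** are 300 ms at baseline, 15 ms faster for
  angry/push, and 20 ms faster for angry-male and happy-female faces.
  **Female boundaries** are 1.20 at baseline, 1.26 for angry-male and 1.25
  for happy-female faces. Male participants have flat `a = 1.20`,
  `Ter = 0.30 s`.
- **Between-participant structure**: each participant draws a shared
  intercept for `v`, `a`, `Ter` (SDs 0.55, 0.10, 0.040) plus independent
  per-condition jitter (SDs 0.12, 0.03, 0.012). The intercept cancels in
  within-participant contrasts; the jitter does not. Combined with the EZ
  estimation noise at 32 trials per cell (empirically ≈ 0.42 on drift),
  this reproduces per-condition drift SDs near the published ≈ 0.66 while
  keeping within-participant effects detectable at the study's sample
  size.
- **Contaminants**: 3% of trials have their RT replaced by a uniform draw,
  half on [50, 199] ms and half on [2501, 4000] ms, exercising both tails
  of the analysis window and mirroring the ≈ 3% removal rate the window is
  designed to produce.
- **BIS/BAS**: totals are drawn from gender-specific truncated normals
  whose *truncated* means equal the target group means (female BIS 23.32,
  male 19.29; BAS 12.48/13.30), solving for the parent location
  numerically. BIS lives on [7, 28] (1–4 item scoring of 7 items); BAS
  subscales are scored 0–3 (Drive and Fun Seeking on [0, 12], Reward on
  [0, 15]) so that the BAS total — defined as the sum of the subscale
  draws — can attain its target mean. Totals are kept continuous rather
  than integer-rounded; nothing downstream depends on integrality.
- **Trait moderation**: for female participants, the happy/pull
  non-decision time increases by 0.12 s per unit of BIS standardised to
  2 SD. This couples high behavioural inhibition to a damped approach
  advantage and maps one-to-one onto the ex-Gaussian µ regression slope
  the trait analysis estimates (a drift-based coupling of equal RT effect
  would need implausibly large drift shifts).

What the generator does **not** emulate: practice-block learning, RT
autocorrelation and fatigue drifts, lapses or fast guesses beyond the
uniform contaminants, item-level questionnaire structure, and any
real-data deviation from the Wiener process itself. Passing tests
therefore certify the pipeline's correctness and calibration under the
model's own assumptions, not the adequacy of the diffusion model for any
particular empirical dataset.

## Preprocessing rules

Participants with a main-block error rate strictly above 45% are excluded
first, using unfiltered trials (the error screen targets task compliance,
so contaminated trials should count against it); then RTs outside
[200, 2500] ms are removed (bounds inclusive, per the strict-inequality
reading of the rule); then per-participant cell summaries are computed
from correct main-block trials only, with the n−1 variance denominator.
Practice trials never enter any analysis. The EZ cell granularity is the
full three-factor cell (32 trials), matching the four-way ANOVAs
downstream.

## Bayes factors, effect sizes, HDIs

ANOVA-style terms are scored by the BIC approximation
`BF10 = exp((BIC_null − BIC_term)/2)`, with both models fitted by maximum
likelihood as linear mixed models with a participant random intercept and
the term entering as one sum-coded product column. The dv is standardised
before fitting (BIC differences are invariant to affine transformations;
the standardisation only improves optimiser conditioning). This is a
deliberate, documented stand-in for full JZS mixed-model Bayes factors:
it is self-contained, fast, seed-free and testable, at the cost of not
matching any particular g-prior package numerically. Simple-interaction
follow-ups within one participant-gender group use the same BIC route on
the group-restricted 2 × 2 table.

One-sample follow-up tests use the exact JZS Bayes factor: a Cauchy prior
with scale √2/2 on the standardised effect, written as a normal mixture
over `g ~ InverseGamma(½, ½)` and integrated by adaptive quadrature
(relative tolerance 1e−8). The implementation is verified against an
independent noncentral-t × Cauchy quadrature to 4 significant digits.
Effect sizes are `dz = mean/SD` of the paired differences; their 95% HDI
comes from 100,000 exact posterior draws under the Jeffreys prior
(`σ² ~ (n−1)s²/χ²_{n−1}`, `µ|σ ~ N(x̄, σ²/n)`, `δ = µ/σ`), with the
narrowest-interval search over sorted draws. Evidence bands: anecdotal
(1, 3.2], moderate (3.2, 10], strong (10, 100], decisive (> 100); band
edges belong to the lower band, and BF ≤ 1 is labelled "favours null"
with the reciprocal banded the same way.

## Regression models

Accuracy is modelled at trial level (Bernoulli) rather than as aggregated
binomial counts — the likelihood is equivalent and the clustering
simpler. The GEE uses an exchangeable working correlation over
participants, sandwich standard errors, and sum-coded predictors so
coefficients read as ANOVA-style effects; with singleton clusters it
collapses exactly to ordinary logistic ML (tested to 1e−6). Simple-effect
contrasts are Wald tests on linear combinations of coefficients.

The trait analysis models correct-RT distributions as ex-Gaussian
(Gaussian ⊛ exponential; density evaluated in log space via `log Φ` for
stability). The Gaussian mean µ is a linear function of the
treatment-coded expression × response × participant-gender × covariate
factorial (reference levels angry/push/male; covariate mean-centred and
scaled to 2 SD, so its slopes are per-2-SD effects), plus fixed
per-participant intercept offsets, with σ and τ shared. This deliberately
simplifies a random-slopes mixed model — a research project in itself —
while preserving the estimand of interest, the 4-way µ-slope. Terms
constant within a participant (gender, covariate, and their product) are
absorbed by the intercept offsets and excluded. Fitting is L-BFGS-B on
(β, log σ, log τ) with fully analytic gradients; standard errors come
from the observed information (finite differences of the analytic
gradient). Starting values are moment-based
(`τ₀ = (skew · VRT^{3/2} / 2)^{1/3}`, floored away from zero).

## Fit assessment

For every non-degenerate cell estimate, 10,000 trials are simulated from
the fitted `(v, a, Ter)` (configurable; tests use fewer) and compared to
the observed cell: medians and 5th/95th percentiles (linear interpolation
between order statistics), separately for correct and error streams. The
band check asks whether the observed median lies inside the
predicted 5–95% band; the plot mirrors the usual presentation with
observed percentile bars. Cells with no observed errors are reported as
not assessable for the error stream. Negative flagged `Ter` estimates are
floored at 0 for simulation only. Under self-consistent simulation the
correct-stream coverage exceeds 0.9 (a tested property).

## Problem sizes and numerical choices

Calibration and recovery checks run at 50,000 trials per parameter point,
where Monte-Carlo error on recovered drift is ≈ 0.013 — comfortably
inside the ±0.05 recovery tolerance. The end-to-end detection property
runs the full 32 + 32-participant pipeline over 20 seeds and asks for the
female drift interaction at BF > 10 and the male at BF < 3.2 in at least
80% of them. Unit tests use 6 participants per gender. Sub-seeds for
pipeline stages are derived from the master seed and the stage name
(CRC32 into a `SeedSequence`), so adding a stage never perturbs earlier
streams.

## Known limitations

- The BIC-approximation Bayes factors are not numerically comparable to
  JZS mixed-model packages; only the exact one-sample JZS test is.
- The EZ estimator is moment-based: at 32 trials per cell, drift
  estimates carry sampling SD ≈ 0.4 and a small upward bias; analyses at
  this granularity inherit that noise (as any application at this design
  size would).
- The ex-Gaussian regression's fixed participant intercepts cannot
  estimate between-participant terms (they are absorbed); only
  within-participant interactions with the covariate are identified.
- The error-response stream of the fit check is expected to fit worse
  than the correct stream whenever real data depart from the
  symmetric-start assumption; the package reports this rather than
  modelling it.
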