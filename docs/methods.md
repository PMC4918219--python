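# Methods

## The model

Two objects A and B (A the smaller) are judged for relative weight. All
quantities are natural-log ratios: `v = ln(V_A/V_B)` (volume),
`d = ln(d_A/d_B)` (density), `w = ln(w_A/w_B)` (weight), with the exact
constraint `w = v + d`. Positive `w` means the smaller object is felt or
expected to be heavier — the size-weight illusion (SWI) range.

Density is not directly sensed. The observer entertains three
categorical hypotheses about the density relationship and weighs them
against the evidence:

- **R1** — equal density (`d = 0`, so `w = v` exactly);
- **R2** — the smaller object is denser (`v`–`d` correlation `rho2 < 0`);
- **R3** — the larger object is denser (`rho3 > 0`).

Each hypothesis is a bivariate Gaussian over `(v, d)` with mean zero
(plus an optional offset `mu_d_R2` on `d` under R2) and covariance
`[[sv2, rho*sv*sd], [rho*sv*sd, sd2]]`; under R1 `sd = 0`, implemented
as an exact 1-D model rather than a near-singular 2-D Gaussian.

**Vision.** The visual system estimates the volume ratio with power-law
compression, `v* = 0.704 * ln(V_A/V_B)`, and noise `sigma_y2`. The
measurement is taken directly as the observer's belief about the volume
ratio, `v ~ N(y, sigma_y2)`; no additional shrinkage toward the volume
prior is applied. This choice is deliberate: it makes the no-haptic
expected weight track the visually estimated volume relationship
exactly under the dominant equal-density hypothesis, which is the
published behavior of the model (the prediction vector below), whereas
a shrinkage stage systematically overshoots it.

**Per-hypothesis expectation.** Combining the visual belief with the
conditional density prior `p(d | v, R)` and pushing through `w = v + d`
gives one Gaussian per hypothesis:

    p(w | R, y) = N( k_R * y + mu_R ,  k_R^2 * sigma_y2 + (1 - rho_R^2) * sd2 )
    k_R = 1 + rho_R * sd/sv          (k = 1 for R1)

With the defaults `k_R2 = -0.129`: under "smaller is denser" the
expected weights nearly equalize regardless of the size difference.

**Haptics and arbitration.** Lifting supplies `x ~ N(w_true, sigma_x2)`.
Each hypothesis's expectation is updated by precision weighting, and the
hypotheses are arbitrated by the predictive likelihood

    p(x | R, y) = N(x; k_R y + mu_R, k_R^2 sigma_y2 + (1-rho_R^2) sd2 + sigma_x2).

The percept is the mode (MAP) of the arbitrated mixture. Two
arbitration rules are implemented:

- `"likelihood"` (default): mixture weights are the normalized
  predictive likelihoods — structurally, equal a-priori weighting of
  the three hypotheses at the arbitration stage. This is the rule under
  which the package reproduces the published quantitative results: the
  SWI appears for five of six cube pairs at the default parameters,
  grows with the volume ratio, and collapses for the closest pair when
  visual noise is lowered to 0.05 — the published exception pattern.
- `"posterior"`: weights `p(R|x,y) ∝ p(x|R,y) p(R)` including the
  hypothesis priors (0.8, 0.15, 0.05). This textbook rule is exposed
  and fully supported (and `hypothesis_posterior` always computes it),
  but with the default priors the equal-density hypothesis dominates
  arbitration so strongly that the illusion survives only for the most
  discrepant pair — it cannot reproduce the published predictions.

Without lifting (`Expectation` condition) there is no haptic factor and
the percept is the MAP of the prior-weighted mixture of the visual
expectations. Haptic absence is an explicit argument (`x=None`), never a
literal infinite variance.

**Reporting scale.** Internally everything is the canonical log ratio.
The published no-lift prediction vector is on the *ratio* scale
`exp(w_hat)` in the smaller/larger convention, ordered by ascending
volume ratio of the smaller to the larger cube: the model yields
(0.098, 0.231, 0.231, 0.425, 0.425, 0.551) against the published
(0.01, 0.23, 0.23, 0.43, 0.43, 0.55). Five entries agree to ±0.007;
the first published entry (0.01) is not reproducible under any
formulation we tried — every variant gives ≈ exp(v*) = 0.098 for that
pair, and we treat the published 0.01 as a likely misprint of 0.10.
Equal volume ratios give equal predictions exactly (the pairs'
side lengths double exactly; the printed volumes agree to rounding).

## Default parameters

| name            | default | meaning                                         |
|-----------------|---------|-------------------------------------------------|
| sigma_y2        | 0.10    | visual noise variance of the log volume ratio   |
| sigma_x2        | 0.50    | haptic noise variance of the log weight ratio   |
| sigma_v2        | 0.85    | prior variance of `v`                           |
| sigma_d2        | 1.2     | prior variance of `d` under R2/R3               |
| rho2, rho3      | ∓0.95   | prior `v`–`d` correlations                      |
| prior_R         | 0.8/0.15/0.05 | hypothesis priors p(R1), p(R2), p(R3)     |
| volume_exponent | 0.704   | visual volume compression                       |
| mu_d_R2         | 0       | density-asymmetry offset under R2 (log units)   |

All are dimensionless (log-ratio space). The defaults are the published
settings; `predict` with no arguments reproduces the headline
predictions.

## Known deviations from the published claims

Three published claims do not follow from the printed equations and
parameters, under this or any of the eight structural variants we
evaluated, and are left as failing checks rather than patched:

1. the closest pair (7.62 vs 10.16 cm) shows a weakly *negative*
   percept (≈ −0.20) at the defaults, i.e. no illusion; the published
   text implies it is positive everywhere except two boundary settings;
2. at prior correlation magnitude 0.75 the R2 slope `k_R2` changes sign
   (at `|rho| = sv/sd ≈ 0.84`), so the illusion fails for *all* pairs,
   not only the closest one;
3. the published robustness ranges for `sigma_d2` (down to 0.9) and
   `sigma_v2` (up to 1.1) cross the same sign boundary
   (`sd > sv/|rho|`, `sv < |rho| sd`), where the model cannot produce
   the illusion for the closer pairs.

The acceptance suite encodes the published claims verbatim, so these
appear as expected test failures, cell by cell.

## Synthetic observers

A simulated observer is the percept model plus a log-normal report
stage: `report = exp(percept + eps)`, `eps ~ N(0, 0.21^2)`. The 0.21
default equals the published within-subject variability of log reports;
it is calibrated to the *total* trial-to-trial variability, so the
default simulation mode evaluates percepts at the sensory means
(`y = v*`, `x = w_true`) and lets the report noise carry all
variability. A fully stochastic mode (sampling `y` and `x` per trial)
is available; because the MAP readout is nonlinear, that mode biases
mean log reports of the closer pairs toward the expectation-dominated
side and inflates within-subject variability to ≈ 0.59 — a real
property of MAP-readout models worth knowing before comparing simulated
and empirical means.

Designs follow the behavioral protocols: Lifting sessions have 144
trials (12 ordered size pairs × 3 weight classes × 4 repeats, equal
weights within a pair), Expectation sessions 128 trials (12 ordered
pairs × 8 plus 4 identical-size controls × 8). Cohorts are seeded with
one master seed; per-subject streams derive from
`(master_seed, subject_id)` so cohorts are reproducible under resizing.

**Individual differences.** Observers differ in `mu_d_R2` — the degree
to which they believe a smaller object to be denser. The default
cohort draws `mu_d_R2 ~ Uniform(0, ln 2)`: from no asymmetry up to
"twice as dense", the lower half of the two-to-three-fold everyday
asymmetry that the prior correlation itself encodes. Stronger beliefs
push the closest pairs past the turning point where the R2 expectation
becomes too incongruent with the haptic evidence; the
expectation–illusion correlation concerns the rising regime below that
point. The Day-1 "smaller is denser" instruction is modelled as raising
`prior_R2` to 0.9 for the Expectation session only (rescaling the other
priors proportionally); Day-2 lifting uses the unmodified profile.
We model individual differences through `mu_d_R2` rather than
`prior_R2` because under likelihood arbitration the hypothesis prior
does not influence lifting percepts, and because "how much denser"
is a degree, which a prior probability is not.

What the generator does *not* emulate: absolute-mass (Weber) scaling of
haptic noise — hence simulated illusion magnitude cannot vary across
the L/M/H weight classes, unlike the published human data; sequential
trial-to-trial learning; motor/grip dynamics; response quantization on
the 10-unit scale. Passing simulation-based tests therefore says
nothing about weight-class effects or learning dynamics in real data.

## Parameter recovery

`fit_observer` maximizes a Monte-Carlo likelihood: per condition it
samples sensory measurements (common random numbers across candidates),
pushes them through the percept model, and closes the report stage
analytically, so the predictive density of a log report is a mixture of
`N(w_k, noise^2)` kernels. The search is a two-stage grid over the free
parameters (`sigma_x2`, `prior_R2`, `mu_d_R2`, `report_noise_sd`). A
parameter whose profile log-likelihood is flat (range < 0.5) is flagged
non-identifiable — notably `prior_R2` fitted to lifting data under
likelihood arbitration, where it has no influence. The recovery
harness therefore generates and fits its cohorts under the
posterior-arbitration variant, where the hypothesis prior shapes the
lifting percepts and both `prior_R2` (±0.05 at a true 0.15) and
`sigma_x2` (±0.15 at a true 0.5) are recovered from a 30-subject,
144-trial-per-subject cohort.

## Numerics

- MAP search: dense grid on `w ∈ [−6, 6]` at step 1e-3 with parabolic
  refinement around the best cell; ties broken toward the smallest
  `|w|` so symmetric inputs give exactly 0. Mixtures of three Gaussians
  can be multimodal; the grid is the reference policy.
- Batched percepts (simulation, fitting) use a damped-Newton ascent on
  the log mixture density started from every component mean; agreement
  with the grid is a tested invariant (<2e-3).
- The validation oracle integrates the generative chain over `(v, d)`
  numerically (step 0.01, half-width ≥ 10, widened until every
  component's ±7 sd tail is covered; boundary mass > 1e-4 is an error).
  Closed-form means agree with it to 1e-3 absolute, variances to 1e-3
  relative, MAPs to the oracle grid resolution, on 100+ randomized
  parameter draws.
- Degenerate inputs: `sigma_d2 = 0` collapses R2/R3 onto R1 (equal
  likelihoods return the priors unchanged); `sigma_x2 → 0` returns the
  haptic evidence; identical-size pairs give exactly 0. Exact object
  swap (antisymmetry, with R2/R3 exchanging roles) holds whenever
  `mu_d_R2 = 0` and is property-tested.

## Limitations

- The closest cube pair sits on the wrong side of the arbitration
  boundary at the default parameters (deviation 1 above); conclusions
  about near-threshold pairs should not rely on this implementation's
  sign there.
- The likelihood arbitration rule is a reconstruction: it is the unique
  variant among those evaluated that reproduces the published numbers,
  but it is not the textbook posterior rule, and both are exposed.
- Weight-class effects are out of reach by construction (ratio-based
  model, no Weber scaling).
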