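# Methods

This note documents the models behind `dazzletrack`, the defaults and why
they were chosen, and what the synthetic pipeline can and cannot say about
real observers.

## Stimulus world

Squares perform a correlated random walk: per frame, heading increments are
drawn from a wrapped normal with mean 0 and SD π/8 rad (a value small enough
that wrapping is numerically negligible, though it is always applied), and
the square advances `speed / frame_rate` = 2 px along the new heading. The
heading update precedes displacement within a frame, so the first step of a
trial is already correlated with the initial heading.

Three choices the task description leaves open are fixed as follows:

- **Containment.** Agent centers are confined to the arena inset by half a
  square, so the square body stays inside. A step that would exit has the
  offending displacement component mirrored and the heading re-derived
  (specular reflection). This conserves speed exactly at every frame —
  including boundary frames — and avoids wall-sticking. Clamp or wrap rules
  could be swapped in behind the same `step` contract.
- **Initial placement.** Uniform positions in the (inset) arena interior and
  uniform headings, from a seeded stream. A soft capacity check (total
  square area ≤ arena area) bounds the group size.
- **Overlap.** Squares neither collide nor avoid one another; at large group
  sizes in a 268×268 px arena, heavy overlap is an intended feature of the
  crowded display.

Each agent draws turns from its own seeded substream, so a given agent's
trajectory does not depend on how many other agents are simulated.

## Textures and rendering

Gratings use luminances `mean·(1 ± contrast)`, giving Michelson contrast
exactly equal to the nominal value (1.0 → levels 0 and 142.8 around mean
71.4); the 8 px wavelength yields 4 full periods across a 32 px square, and
the two phases (0°/180°) are complementary band swaps. Trinary textures draw
each 4×4 element iid from {35.7, 71.4, 107.1}, so targets and background
share the same mean and level set.

Rotation to heading uses nearest-neighbor resampling: it preserves the exact
luminance set (bilinear would synthesize intermediate values and dilute
contrast), and quarter-turn rotations are exact grid rotations. Pixels
outside the rotated square's support show the background. The trinary
*target* texture rotates with heading like the gratings — orientation
locking applies to the square, not to a particular pattern. Per-square
grating phase and the trinary background are drawn once per trial and held
static within it. Raster values are abstract floats on the stated luminance
scale; PNG export maps [0, 142.8] → [0, 255] linearly. Display calibration
(gamma, photometry) is out of scope.

## Sessions and the error metric

A session is 6 randomly ordered blocks (coloration × background), each
containing the 7 group sizes × `reps_per_size` in random order. The default
`reps_per_size = 8` follows from the stated session length: 336 trials over
6 blocks and 7 sizes forces 8. Four practice trials precede the session and
are flagged, never analysed. The target is chosen uniformly among the
squares, seeded; the 1000 ms highlight is modeled as (a) the unscored
initial window and (b) the observer knowing the target identity at t = 0 —
no visual highlight is rendered in the default pipeline.

Tracking error is the arithmetic mean of center-to-center Euclidean
distances over samples with 1000 ms ≤ t < 5000 ms (400 samples at 10 ms),
computed in continuous coordinates. It is translation invariant and scales
with any common rescaling of both trajectories. Zero error — possible only
for an idealized noiseless observer — is rejected with a warning before the
log transform rather than offset-corrected.

## The mechanistic observer

The cursor agent maintains a *believed target*, initially the true one. At
each 10 ms sample, if m ≥ 1 distractors lie within `swap_radius` (60 px) of
the believed target, belief swaps to the nearest of them with probability

    p = min(1, swap_base_rate · Δt · multiplier(condition) · confusion_gain^(m−1)).

The cursor sits on the believed target's position `lag_ms` earlier plus
isotropic Gaussian jitter. Defaults: lag 80 ms, jitter SD 4 px, base rate
0.12 s⁻¹, gain 1.30, with condition multipliers that make parallel-striped
conditions modestly more swap-prone (1.3–1.4×).

The base rate and gain were chosen so that the expected number of belief
losses per trial stays well below saturation across group sizes (~0.3 at
group size 10, rising to a few at 60). Once belief is lost, mean error
approaches the distance between two random arena points regardless of group
size; rates high enough to lose the target early at *every* size would
flatten the error–group-size curve at that asymptote. Operated away from
saturation, mean error rises strictly with group size because neighbor
counts — hence swap opportunities — do; this is the qualitative confusion
effect, emerging from the mechanism rather than being scripted. Nothing
here is claimed as the mechanism of human tracking; the agent only shares
its statistical signature.

## The generative observer

`generate_error_table` draws
`log(error) = Xβ + b_participant + ε`, with `b ~ N(0, σ_p²)`,
`ε ~ N(0, σ_r²)`, and X exactly the model-4 design (target + background +
quadratic number + target × number, treatment-coded against trinary/plain).
Errors are therefore log-normal within cells, participants are
exchangeable, and fixed-effect recovery by the fitting stage is
basis-aligned by construction.

The default coefficients are configuration, not estimates (no coefficient
table exists to copy): intercept 3.40 (~30 px), number terms +0.35 / −0.10
on the standardized orthogonal polynomial, parallel main effect +0.08,
trinary-background effect +0.05, parallel × number interactions +0.12 /
−0.04, zero orthogonal effects (orthogonal ≡ trinary — the merged-coding
truth), σ_p = 0.25, σ_r = 0.50. Magnitudes were set so errors span a
plausible ~20–60 px range and the interaction is decisively detectable at
the full session size (16 × 336) while AIC selection becomes unreliable for
few-participant sessions.

## Model ladder and AIC

Group size enters through an orthogonal polynomial basis built over the
seven canonical sizes with equal weight (centered, unit SD, fixed by the
design rather than the data), for numerical stability; AIC and fitted
values are basis-invariant. Factors are treatment-coded (reference:
trinary coloration, plain background); any full-rank coding gives the same
likelihood, which a test asserts.

All fits are maximum likelihood (statsmodels `MixedLM`, `reml=False`)
because the candidates differ in fixed effects and REML likelihoods would
not be comparable. `k` counts fixed coefficients plus the two variance
components, so the seven candidates carry 14, 20, 16, 14, 12, 8 and 9
parameters; one test cross-checks a fit's log-likelihood, AIC and df
against `lme4::lmer` via Rscript. Convergence warnings (e.g. boundary
estimates when the true participant variance is zero) are attached to the
`FitResult` rather than raised; a failed fit is excluded from the
comparison with a logged reason.

`AICTable` reports both the raw AIC minimum and a parsimony selection:
among models within ΔAIC < 2 of the best, prefer the fewest parameters.
The latter mirrors how such ladders are read in practice and is what the
model-recovery experiment scores. A generalized-least-squares re-analysis
relaxing compound symmetry is a possible extension, not implemented.

Within-subject CIs use Cousineau participant-centering with the Morey
correction `sqrt(C/(C−1))` over the C = 42 design cells, on per-participant
cell means, with a t critical value at (participants − 1) df.

## Reproducibility

A root seed deterministically spawns per-stage, per-participant and
per-trial streams (`numpy.random.SeedSequence`); all derived seeds stay
below 2³¹. Reruns with the same config produce bit-identical tables, and
the run manifest records the seed, a config hash, and package versions.

## What the synthetic data do and do not show

The generative observer has, by construction, exactly the covariance
structure the mixed models assume (compound symmetry, log-normal errors,
shared residual variance across cells). Passing recovery tests therefore
demonstrates that the analysis machinery is correct and well-calibrated —
not that real observers satisfy those assumptions. The mechanistic agent
relaxes this (its errors are bounded by the arena and its variance grows
with group size) and is the harder, model-misspecified road test; it has no
fitted relationship to human data. Monte-Carlo suites use 25–200 replicates
per condition, sizes chosen to keep the full test run within a few minutes
while leaving comfortable statistical margins.
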