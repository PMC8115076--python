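# Methods

This note documents the models, the synthetic-stimulus generator, the
numerical choices, and the design decisions behind `ltbseg`, in enough
detail to reconstruct any result the package computes.

## Stimuli

All stimuli are `image_size × image_size` luminance arrays in [0, 1] on a
mid-gray (0.5) background, pixel-centered coordinates with the origin at the
image center. A boundary is a ±45° line through the origin; the two
diagonals have integer signed coordinates `d = y − x` (right-oblique) and
`d = y + x` (left-oblique), so "pixels exactly on a diagonal" is a
well-defined set, excluded from both halves wherever halves are compared.

**Disc geometry.** The stimulus disc has radius `image_size/2 − 4` px
(124 px in the standard 256-px frame) with a raised-cosine taper over its
outer `taper_width` px (default 16). The frame-to-disc mapping (4° of
visual angle in the original experiments) is metadata only; pixels are the
native unit.

**Texture boundaries (LTB).** Each side of the boundary receives `n_p`
micropatterns — unit-peak Gaussian blobs (σ = 2 px) truncated to a 9 × 9
support and scaled to peak amplitude ±A (white/black). The proportion
π_U of unbalanced micropatterns sets the cue: the unbalanced ones take the
side's majority polarity (which side is brighter is the phase, randomized
per trial), the rest split equally between white and black. `π_U · n_p`
must be a whole multiple of 4; requested values snap to the nearest
feasible level (recorded in metadata) or are rejected with `snap=False`.

Placement is sequential rejection sampling, deterministic given the spec
seed, under three constraints:

1. *Quadrant balance:* every polarity class on each side splits equally
   between the side's two quadrants (the regions cut by the anti-diagonal).
2. *Diagonal clearance:* every pixel of a blob's 9 × 9 support lies
   strictly on its side of **both** diagonals (|d| ≥ 9 at the center).
3. *Non-overlap:* centers keep a Euclidean distance ≥ 8 px (one footprint
   diameter), and ≥ 4 px clearance from the taper.

Constraints 1–2 make the luminance difference across the anti-diagonal
**exactly zero** (to 1e−12) for every seed: each blob's truncated mass is
identical and lies wholly within one quadrant, and quadrant counts cancel
by construction. Constraint 3 guarantees no blob's support contains another
blob's center pixel, so the pixel extrema are exactly 0.5 ± A and the
Michelson contrast is exactly 2A. A 4-px exclusion radius was considered
and rejected: it lets same-polarity Gaussian tails sum to ~1.14·A between
close centers, breaking both identities. Corners of two supports can still
overlap at distance 8; the resulting cross-term makes RMS contrast depend
on π_U at the ~3 × 10⁻⁴ relative level (exactly zero dependence would need
fully disjoint supports, which is infeasible at `n_p = 64`). Tests treat
RMS-contrast invariance to π_U as equality of means to 0.1%.

Placement raises a `PlacementError` after 10,000 failed attempts for any
single blob (density too high for the geometry).

**Step boundaries (LSB).** `luminance = 0.5·(1 + s·c_M·sign(d)·taper(r))`
with phase sign s = ±1; phase 180 is the 180° rotation of phase 0, and the
pixel extrema give Michelson contrast exactly c_M. The texture field is
*not* attenuated by the taper (blob supports stay inside the full-amplitude
region); the taper belongs to the step stimulus and to the disc mask.

**Composites.** Deviations from mid-gray add and clip to [0, 1]; the
clipped-pixel count is recorded (zero at all study contrasts). Relations:
`neu` (no masker), `con_0` / `con_180` (same orientation, same/opposite
phase), `inc` (orthogonal orientation). Inconsistent relation/orientation/
phase combinations are rejected.

**Ladders.** π_U: nine evenly spaced levels 0…1 (steps of 0.125, the
feasible grid at `n_p = 32`). c_M: eleven logarithmic steps from 10^−2.7 to
10^−1.7.

## Features

`L_R`, `L_L` are the absolute differences of mean luminance between the two
half-discs cut by each diagonal, over the disc mask; means (not sums) keep
the scale image-size-independent, and any remaining scale convention is
absorbed by model gains. `C` is RMS contrast, SD/mean of the masked pixels;
computed over the disc only, since the constant background would dilute it
by an arbitrary factor.

## Observer models

**SDT.** `P_C = λ/2 + (1−λ)·Φ((g·x)^τ / 2)`; λ ∈ [0, 0.1] is a lapse rate.
Φ is the standard normal CDF (erf-based).

**IC-SDT / IC-1.** The image-computable d′ is
`(g₁L)^{τ₁} / (1 + (g₂C)^{τ₂})`; `g₂ = 0` recovers the additive form. The
general one-stage decision is `u = (g₁L_R)^{p₁} − (g₁L_L)^{p₁}` (each term
divided by the same normalization denominator in the divisive variant) with
`P(R) = Φ(u)`. On stimuli with a zero anti-diagonal difference the two
coincide under the gain mapping `g_SDT = 2^{1/p₁}·g₁`, which absorbs the
d′/2 halving — verified numerically in the tests.

**IC-2 (filter–rectify–filter).** The deviation image is convolved with an
ON-center difference-of-Gaussians kernel `h = c − ρ_IE·s` (unit-amplitude
Gaussians; σ_c = 4 px matching the micropattern radius, σ_s = 2σ_c,
support half-width 16 px); the OFF kernel is −h. Outputs are half-wave
rectified and raised to p₁ pointwise (`rectify_then_pool`, the default; a
`pool_then_rectify` order is available), pooled uniformly per diagonal
half, and the absolute ON/OFF pool differences feed the second stage
`u = (g₂L_R^{ON})^{p₂} + (g₂L_R^{OFF})^{p₂} − (g₂L_L^{ON})^{p₂} −
(g₂L_L^{OFF})^{p₂}`, `P(R) = Φ(u)`.

Two properties of this cascade matter for everything downstream:

- *Pool domain.* The second stage integrates over the two half-planes of
  the whole frame (diagonal pixels excluded). Because the first-stage
  response vanishes outside the disc's kernel-width neighborhood, this
  equals uniform half-disc integration over any disc containing the
  response support, up to a constant denominator absorbed by g₂. Restricting
  the pool to an eroded disc instead truncates rim micropatterns' responses
  asymmetrically and injects anti-diagonal channel noise comparable to the
  signal — measurably destroying task performance. Zero padding in the
  convolution is exact, not an artifact: the true background deviation is
  zero.
- *Discrimination needs p₁ ≠ 1 at DC balance.* The kernel sum crosses zero
  at ρ_IE ≈ 0.271 for the default discrete support (the balance point
  depends on support truncation). At balance with p₁ = 1, every isolated
  blob — white or black — contributes the *same* rectified pooled mass to
  the ON (and OFF) channel, because the positive and negative lobes of the
  blob response carry equal mass; with equal blob counts per side the
  decision variable is ~0 at any π_U. The channels differ in lobe *shape*
  (tall-compact center vs. broad-shallow ring), so an expansive p₁ > 1 (or
  compressive p₁ < 1) breaks the degeneracy. Simulated DC-balanced
  observers therefore use p₁ = 2. Off balance, the net DC response itself
  carries the polarity signal and p₁ = 1 suffices.

At the balance point the cascade is blind to a uniform luminance pedestal;
the finite frame limits this exactness to stimuli whose response support
stays a kernel half-width clear of the frame border (the toy stimuli in the
tests do; a full-frame disc leaves an interaction of order 10⁻² in P(R)).

## Fitting

All fits maximize a log-likelihood in nats — binomial per level for the
psychometric function, Bernoulli per trial for image-computable models —
with probabilities clamped to [1e−9, 1−1e−9]. Optimization is L-BFGS-B on
log-transformed gains and exponents (bounds: gains [1e−6, 1e4], exponents
[0.1, 10], λ ∈ [0, 0.1]), launched from a grid of start points; the best
start wins. Degenerate data (all correct or all wrong at every level, zero
trials, a single level) are refused with informative errors.

The IC-2 fit is a nested profile search: ρ_IE over the grid 0.10–0.40 in
steps of 0.05 (extended one step at a time toward 0.0 or 1.0 whenever the
optimum lands on a grid end); for each ρ_IE, p₁ by coarse grid {0.5, 1, 2}
plus bounded 1-D refinement on log p₁ (p₁ enters only through the pooling
step, so each candidate costs one rectification pass over cached
center/surround convolutions — the DOG's linearity in ρ_IE means each image
is convolved only twice in total); for each p₁, (p₂, g₂) by L-BFGS-B from
the 3 × 5 start grid (p₂ ∈ {0.5, 1, 2}, g₂ ∈ 10^−3…10^1 in 5 log steps) on
the pooled channel responses, rescaled to unit median so the gain grid is
meaningful at any pool scale. K = 4.

Identifiability: near p₂ = 1 the second-stage exponent trades off against
g₂ and is only weakly constrained by 600 trials (its profile likelihood is
flat); ρ_IE, p₁ and g₂ recover sharply. Recovery tests use a factor-two
band for p₂ and ~25–35% bands for the others, matching the replicate
spread.

Thresholds invert the fitted psychometric function at 75% correct
(lapse-aware). Bootstrap CIs are parametric: correct counts redrawn as
`Binomial(n_i, p_i)` per level from the observed proportions, refit B times
(default 200), percentile 95% intervals for parameters and threshold;
failed refits are counted, fully degenerate inputs flagged. The bootstrap
RNG is seeded independently of the stimulus RNG.

`BIC = ln L − (K/2)·ln n`; larger is better, and exp(ΔBIC) is a posterior
odds ratio.

## Experiments

**Staircase.** Standard 1-up-2-down on a discrete sorted ladder, one index
per move, clipped at the ends, starting at the highest level; true
orientation and phase randomized per trial; reversals logged at direction
changes. The rule equilibrates where p² = ½, i.e. at 70.71% correct. The
convergence check runs a fine ladder (201 levels, step 0.005) for 10⁵
trials and averages an even number of reversal levels after a 10-reversal
burn-in — at 10⁴ trials the estimator's Monte-Carlo spread exceeds the
±0.5 pp check band, so the run length was raised until the estimator itself
is precise (~2 s of CPU).

**Masking experiment.** Constant stimuli with counts 200/100/100/200 for
neu/con_0/con_180/inc per run (configurable), orientations balanced within
condition to ±1 trial, target phase random, stimuli built by the generator,
full replay determinism from the master seed. The texture target is
presented at a just-noticeable π_U and the masker at a just-noticeable c_M.
Simulated-observer calibration mirrors the human protocol: targets at
π_U = 0.25 (the feasible level nearest the ~0.3 median human threshold) and
the masker at the *one-stage* observer's own step-boundary threshold
(c_M ≈ 0.005, the human-scale value) — the step threshold belongs to the
edge mechanism that the one-stage model stands in for, not to the texture
mechanism, whose own step threshold is ~8× higher. Gains are calibrated so
each observer performs ≈78% correct on neutral trials.

Under these conditions the package reproduces the signature dissociation:
a DC-balanced IC-2 observer shows no neutral-vs-incongruent accuracy
difference; a neutral-matched IC-1 observer collapses to near chance under
an orthogonal masker (its two cues null each other at threshold by
construction); an IC-2 observer with a net-positive DC first stage performs
better for phase-aligned than opposite-phase congruent maskers.

## Simulation sizes

Full stimulus scale (256 px, `n_p = 32`) is used for stimulus identities,
model equivalences, and the masking signatures. The expensive fitting
studies (IC-2 recovery, BIC model selection across 10 replicates) run at a
reduced geometry — 128 px frame, 60 px disc, 8 px taper, `n_p = 16`,
π_U = 0.5 targets, maskers at each generating observer's own threshold —
chosen so the full suite completes in ~10 minutes on one CPU while
preserving every qualitative property tested at full scale.

## What the generator does and does not emulate

The synthetic stimuli reproduce the construction rules of the original
displays: micropattern geometry, quadrant balancing, non-overlap, discrete
π_U grid, tapered step edges, and the masking superpositions. They do not
emulate display gamma, monitor noise, fixation jitter, temporal envelopes,
or natural-texture statistics; simulated observers respond by the models'
own Bernoulli draws, with no sequential dependencies, lapses (unless
modeled), or learning. Passing tests therefore certify the models and
machinery, not human behavior: the package's claims about humans are
limited to reproducing the published pooled statistics from their printed
proportions (integer-rounded counts, Pearson χ² without continuity
correction — the no-correction choice is validated by exact agreement with
the printed values).

## Known limitations

- The DC-balance value of ρ_IE depends on the discrete kernel support
  (0.271 at the default); published descriptions of comparable filters
  place it near 0.3 under an unstated support.
- The first-stage rectification order is configurable because the
  composition "rectified … with nonlinear exponent" is ambiguous;
  rectify-then-pool is the default and the only order used in results.
- p₂ is weakly identified near 1 (see Fitting).
- The uniform-offset blindness of the balanced cascade is exact only away
  from the frame border.
- SDT observers have no image pathway; in masking simulations they respond
  from the psychometric function at the target level and ignore maskers.
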