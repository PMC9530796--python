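# Methods

## The model

The detector is a four-layer feed-forward pathway closed by a time-delay
feedback loop. All temporal filtering uses causal, discretely sampled
Gamma kernels Γ_{n,τ}(t) = (nt)ⁿ e^{−nt/τ} / ((n−1)! τⁿ⁺¹); each kernel
has unit integral and a single mode at t = τ, with the order n setting its
spread. The stages are:

1. retina: per-frame Gaussian blur (σ₁), modeling the ommatidium's
   acceptance angle, followed by conversion to the internal luminance unit
   (below);
2. lamina: per-pixel temporal band-pass H = Γ_{n₁,τ₁} − Γ_{n₂,τ₂}
   (zero DC: constant scenes produce no signal);
3. medulla: ON channel = positive part of the lamina output; OFF
   channel = magnitude of the negative part, delayed/spread by Γ_{n₃,τ₃};
4. lobula: STMD response = ON × delayed OFF, followed by center-surround
   lateral inhibition (difference of Gaussians σ₂ < σ₃, rectified lobes
   weighted A for the center and B for the surround) and positive
   rectification.

The OFF channel convolves the *magnitude* of the negative lamina lobe, so
OFF ≥ 0 and the lobula product is non-negative. (Rectifying with the
signed negative part would make the product non-positive and the final
rectification would annihilate every response.)

The feedback pathway adds a·(D * Γ_{n₄,τ₄}) to the lamina input, with
a < 0. The feedback signal is computed from the raw lobula product D, not
the post-inhibition output: the closed-loop operator is exactly the
ON × delayed-OFF composition, and lateral inhibition is applied once after
the loop has converged.

## Parameters

| parameter | default | meaning |
|---|---|---|
| σ₁ | 1 px | retina blur |
| n₁, τ₁, n₂, τ₂ | 2, 3, 6, 9 | lamina band-pass (τ in frames) |
| n₃, τ₃ | 5, 25 | OFF-channel delay |
| n₄, τ₄ | 5, 10 | feedback delay |
| σ₂, σ₃, e, ρ | 1.5, 3, 1, 0 | lateral inhibition DoG |
| A, B | 1, 3 | inhibition lobe gains |
| a | −0.3 | feedback constant, 0 < \|a\| < 1, a < 0 |
| tol, max_iter | 10⁻³, 50 | fixed-point stopping rule |
| θ, nms_radius | 10⁻³, 5 px | detection threshold and NMS radius |
| luminance_scale | 32 | internal luminance unit |

Time constants are in sample units (frames): at the benchmark's 1,000 Hz
sampling rate one frame is one millisecond, so the standard values apply
verbatim. The velocity tuning of the model is therefore fixed *in frames*:
with τ₃ = 25, a w-pixel target is optimally detected when it occludes a
pixel for about 25 frames, i.e. at about w/25 px/frame. A and B are not
part of the core parameter table; the defaults follow the directional-STMD
lineage this model extends and are exposed in the config.

### The internal luminance unit

Inputs are luminance volumes in [0, 1]. Internally the retina stage
multiplies by `luminance_scale`, because the lobula product makes the
closed loop *scale dependent*: D grows quadratically with the luminance
unit while P grows linearly, so the effective loop gain is proportional to
the unit. At unit 1 the feedback is numerically inert (inhibition
percentages of order 0.01%); at the full 8-bit unit (255) the fixed-point
iteration leaves its stability region for |a| ≳ 0.2 on high-contrast
scenes. The default of 32 is the largest power-of-two unit for which the
whole studied feedback range a ∈ (−0.5, 0] converges on every fixture,
including worst-case full-contrast scenes, with roughly a factor-two
stability margin — chosen once from that stability analysis.

## The fixed-point solver

The closed loop D = F(P + a·D * Γ₄) is solved batchwise (whole sequence
per iteration) from D₀ = 0; the retina output P is computed once and held
fixed. Iteration stops when the absolute L2 norm of successive iterates
over the whole volume falls below `tol` (default 10⁻³; a relative-residual
option exists for scale robustness). Non-convergence at `max_iter` returns
the best iterate with `converged=False` and a warning. With a = 0 the
operator does not depend on D, so a single pass is returned directly —
bit-identical to the open-loop model.

A sufficient condition for existence/uniqueness follows from a
contraction-style majorization. Writing u = P*H + a·D*V with V = Γ₄ * H,
the operator is F D = (u⁻ * Γ₃) × u⁺, and Cauchy–Schwarz plus Young's
inequality give ‖F D‖ ≤ φ + |a| Q ‖D‖ + a² N′ ‖D‖² with
φ = ‖Γ₃‖₂ ‖P*H‖₂², Q = 2‖Γ₃‖₂ ‖P*H‖₂ ‖V‖₁ and N′ = ‖Γ₃‖₂ ‖V‖₁²,
norms taken per pixel over time with the worst pixel used (the loop acts
independently per pixel once P is fixed). The admissible interval is
a ∈ [−1/(Q + 2√(N′φ)), 0), clamped inside (−1, 0). These constants are a
deliberately conservative reconstruction: they are validated by empirical
convergence sweeps (every a inside the estimated interval converges on the
fixtures), never treated as sharp. In practice the solver converges well
outside the guaranteed interval; the default a = −0.3 contracts by about
an order of magnitude per iteration on the standard cluttered fixture.

Causal filtering uses implicit zero history before frame 0, so the first
frames of every response sit in a start-up transient. The conservative
warm-up window (sum of the kernel supports, 230 frames for the default
parameters) is reported in the diagnostics; detections inside it are
flagged rather than dropped, and evaluation slices it off.

## Synthetic scenes

The generator emulates the classic synthetic benchmark for this model
family: a small dark square (1×1–11×11 px, luminance 0–0.1) translating at
100–330 px/s over a cluttered background panning at 50–180 px/s leftward
or rightward, 300 × 250 px at 1,000 Hz at full scale. Backgrounds are
procedural — seeded multi-octave band-limited noise with small dark
speckles as target-like distractors — so every scene is bit-reproducible
from a seed and carries exact analytic ground truth. Targets are stamped
at nearest-integer positions with no sub-pixel anti-aliasing, which keeps
the ground truth unambiguous.

The desk-scale fixture used throughout the tests is 100 × 100 px ×
300 frames at the same 1,000 Hz. The sampling rate is kept rather than
reduced because the model's temporal tuning is fixed in frames: halving fs
would move a 250 px/s target out of the detector's passband and move slow
clutter into it, inverting the benchmark's scenario. Cost is saved through
resolution and duration instead.

The velocity-tuning diagnostic scenes (single target on a uniform
background) run at 250 Hz, where the probe velocities 60/120/250 px/s span
slow-inside-the-passband to fast-outside-it — the regime in which slow,
strongly responding features receive strong feedback suppression while
fast targets escape it. Durations are half-max pulse widths with
sub-sample interpolation at the crossings.

What the generator does *not* emulate: natural-image statistics beyond a
1/f-like spectrum, photometric noise, motion blur, occlusions, and
luminance-dependent contrast structure. Passing tests therefore
demonstrate the mechanisms (velocity selectivity, size selectivity,
closed-loop suppression of slow clutter) on controlled scenes, not
performance on natural video.

## Detection and evaluation

Detections are voxels of the post-inhibition response above θ that are
local maxima within the NMS radius (Euclidean disk, default 5 px to mirror
the matching gate); among equal-valued peaks within the radius the
smallest row-major index wins. Matching to ground truth is greedy
nearest-first, one-to-one, within a 5 px Euclidean gate; the matching
algorithm is not dictated by the metric definitions, so the greedy choice
is cross-checked against an optimal-assignment oracle on small instances
in the tests. "Actual targets" in the DR denominator counts
targets-per-frame summed over frames, i.e. each frame is a detection
opportunity; scoring is per-frame, with no track linking. DR–FA curves
sweep θ over descending quantiles of the positive peak scores, and
operating-point values (e.g. DR at FA = 15) are linearly interpolated with
clamping at the curve ends.

## Numerical choices

- Gamma kernels are sampled at integer frames, truncated at cumulative
  mass 1 − 10⁻⁴ (cap 10(n+1)τ samples), and renormalized to tap-sum
  exactly 1, preserving the analytic unit integral discretely.
- The band-pass H is built by sampling both Gammas on their common
  (longer) support before differencing; truncating the shorter kernel
  early would leave a spurious uncancelled tail of the wrong sign.
- Temporal convolution runs via FFT along the time axis and is truncated
  to the causal window; the OFF channel clamps at zero to remove
  order-10⁻¹⁶ FFT round-off in an analytically non-negative quantity.
- Spatial convolution uses replicate-edge padding, avoiding the spurious
  dark border that zero padding would present to a dark-target detector.
- Degenerate inputs: a temporally constant sequence is an exact fixed
  point at the first iteration; an all-zero sequence makes the operator
  bound vacuous and the interval estimate returns (−1, 0) with a warning.

## Known limitations

- The feedback benefit on the standard desk-scale fixture is modest: at
  the FA = 15 operating point both open- and closed-loop models saturate
  (DR = 1), and the loop's advantage shows mainly as suppression of slow
  clutter (IP) and at stricter operating points. The full-scale benchmark
  scenes, with denser natural clutter, separate the models more.
- The admissible-interval estimate is conservative by construction; it
  certifies a small interval while the solver empirically converges for
  much stronger feedback.
- No directional selectivity: the model responds to motion in any
  direction, and no track linking is performed across frames.
- Real-video evaluation (generic stacks/videos are readable through the
  CLI) is supported as plumbing but not validated against any external
  benchmark here.
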