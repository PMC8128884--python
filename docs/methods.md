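# Methods

## Measurement model

The quantity of interest is the collective motion of keratinocyte
cells/colonies in a 2-D monolayer culture, observed by phase-contrast
time-lapse microscopy. The reference acquisition protocol images five
randomly chosen dish locations for 4 h at 8-min intervals (31 frames,
both endpoints imaged), starting when the culture reaches ≈50%
confluency. Starting near 50% matters because the motion statistic is
only representative when it is stationary over the capture: denser
cultures (≥70%) show declining motion from contact inhibition, sparser
ones (~30%) show rising motion.

For each consecutive frame pair the **motion speed** is

MS = mean over cell pixels of |d(x)| · s · (60 / Δt)   [μm/h]

where d(x) is the dense optical-flow displacement (px/frame) at pixel x,
the mean runs over the segmented cell area of the pair's first frame,
s is the spatial calibration (μm/px) and Δt the frame interval
(min/frame). All vectors inside the mask contribute — including
sub-pixel ones; there is no ≥1 px cutoff. The capture summary **MMS** is
the arithmetic mean of the MS values, and the per-sample index is the
mean MMS of its imaged locations.

A 31-frame capture has 30 consecutive pairs. The MMS divisor is the pair
count (the mean of the quantities actually measured); a compatibility
flag (`frame_count_divisor`) divides the pair sum by the frame count instead,
a fixed ratio of 30/31 ≈ 0.968, for comparability with analyses that
normalize by frames rather than pairs.

Proliferative capacity is quantified from culture counts as
PD = log₂(N/N₀) population doublings and PDT = I/PD days per doubling
(N₀ inoculated, N harvested, I days in culture). This standard closed
form is adopted for the variables N, N₀, I as defined; MMS is expected
to correlate negatively with PDT. Screening uses a strict rule:
SUBSTANDARD iff MMS < threshold, default 40 μm/h — the empirical minimum
of a healthy standard-protocol cohort in the reference culture system.
The threshold is culture-system specific and must be re-derived for any
other medium, substrate or cell source; it is therefore a parameter
everywhere it appears.

## Segmentation

Cell area is segmented per frame in three steps:

1. **Smoothing** with a normalized 3×3 Gaussian kernel. The kernel sigma
   is not dictated by the protocol; σ = 0.8 is used (close to the
   variance-optimal discrete Gaussian on 3×3 support) and is
   configurable.
2. **Sobel edge magnitude** √(Gx²+Gy²) with the standard ±1/±2 kernels.
   Cells are edge-rich under phase contrast while the background is
   nearly flat, so edge magnitude is the discriminating channel.
3. **Chan–Vese binarization** of the edge image with weights λ₁ = 1.2,
   λ₂ = 1.0, ν = 0.02, μ = 0.8. The edge image is first rescaled to
   [0, 1] by its extrema so the weights act on a fixed intensity scale
   regardless of source contrast.

Numerics of the Chan–Vese evolution (all exposed in `ChanVeseParams`):

- Semi-implicit discretization of the length term (neighbour
  coefficients 1/|∇φ| with the centre pixel treated implicitly), time
  step 0.5, regularized Heaviside/delta of width ε = 1.0. The area and
  fit terms enter explicitly; region means c₁, c₂ are those of the
  crisp partition φ > 0.
- **Initialization** defaults to `"edge-density"`: the Otsu threshold of
  the Gaussian-smoothed (σ = 4) image, scaled by its standard deviation.
  The classical checkerboard start is available but collapses into a
  single phase on speckled edge images: with a symmetric start the two
  region means coincide, λ₁ > λ₂ then pushes the level set uniformly
  negative, and the curvature term finishes the collapse. This is a
  genuine local minimum of the energy (a reference implementation of
  the same functional behaves identically), while the true cell/
  background split has lower energy — so a data-driven start is the
  defensible default.
- **Energy bookkeeping.** Every iterate is scored by the crisp-partition
  energy μ·Perimeter + ν·Area + λ₁Σ_in(u−c₁)² + λ₂Σ_out(u−c₂)² (4-
  neighbour perimeter). The returned mask is the best-scoring iterate,
  so the recorded trace of accepted (energy-improving) iterations is
  non-increasing by construction. Per-step backtracking on the
  regularized δ(φ)|∇φ| energy was rejected: flattening the level-set
  profile changes that energy without moving the contour, vetoing good
  steps.
- Convergence when the mean absolute level-set change drops below 10⁻³
  (cap 500 iterations). A constant edge image is a degenerate two-phase
  problem: an empty mask is returned with a `DegenerateImageWarning`.
- The phase with the larger mean edge magnitude is labelled "cell",
  removing the sign ambiguity of the level set.

Masks carry a systematic boundary halo of ≈2 px: the smoothed Sobel
response extends past the true object boundary, and the energy genuinely
prefers the slightly dilated contour. At native microscope resolution
(colonies of hundreds of pixels) this is negligible; on small synthetic
objects it bounds the achievable IoU (a disk of radius r measures
roughly (r/(r+2))² ). No morphological cleanup is applied by default;
hole filling and small-object removal are available behind a flag.
Frames are not down-scaled by default; an integer `decimation` factor
trades boundary precision for speed on large frames.

**Growth.** The overall cells/colony growth of a frame is
100 × (cell pixels)/(total pixels). The start-condition check passes
when the first frame lies in a configurable band around 50% (default
40–60%) and the series' peak-to-trough change stays below 10% of the
starting value.

## Optical flow

Displacements are estimated with a pyramidal polynomial-expansion
scheme: each image is locally modelled as f(x) ≈ xᵀAx + bᵀx + c under a
Gaussian applicability window (neighbourhood 5 px, σ = 1.1), giving the
per-pixel constraint A d = Δb between the two frames; the constraint is
averaged over a 15-px window and solved as a 2×2 system per pixel, with
3 iterations of warping per pyramid level (3 levels, scale 0.5). These
are the conventional defaults of this algorithm family; all are exposed
in `FlowParams`. The implementation is pure numpy/scipy, which keeps the
statistic auditable and testable; an independent iterative Lucas–Kanade
implementation (scikit-image) is used as a cross-check oracle in the
test suite, never as the measurement path. Flow is computed on the
normalized grayscale frames (not on edge images), and the mask of the
pair's first frame delimits the averaging region, since vectors
originate there. A frame pair with an empty mask yields a missing MS
(NaN) and is excluded from the MMS with a warning — an undefined mean is
not zero.

On band-limited textures the scheme recovers imposed rigid shifts of
0.5–3 px to well under 1% and measures < 0.05 px/frame of spurious
motion on identical frames.

## Statistics

Spearman's ρ (average ranks for ties) with the two-sided t-approximation
p-value summarizes the MMS–PDT association; rank correlation is chosen
because PDT is not normally distributed. The 95% CI transforms ρ with
Fisher's z using the conventional rank-data standard error
1.03/√(n−3); at n = 32 this reproduces published-style intervals for
strong negative correlations to ~10⁻³. A percentile bootstrap CI is
available as an alternative (`spearman_ci_bootstrap`).

## Synthetic data generator

`simulate_sequence` emulates the regime the protocol targets: discrete,
loosely connected colonies at ~30–90% confluency, moving collectively at
a known speed. Construction:

- **Colony field**: periodic Gaussian bumps (one per colony, unit peak,
  radii sized to the confluency budget) plus band-limited boundary
  noise; thresholding the field at the per-frame confluency quantile
  imposes the growth series *exactly*, so the truth growth equals
  `growth_fraction` of the truth masks by construction.
- **Texture**: band-limited random fields (default wavelength 6 px — the
  few-pixel membrane/organelle contrast scale of phase-contrast cells at
  a ×4 objective) fill the colonies; the background is near-uniform.
- **Motion**: all fields are periodic, so translation is an exact
  sub-pixel Fourier shift and wraps toroidally (confluency is conserved).
  Modes: `uniform` (one direction), `per-colony-random` (independent
  directions per colony), `swirl` (circular material motion about the
  image centre, with the exact per-frame chord recorded as truth).
- **Noise**: i.i.d. Gaussian, default sd 0.01 on the [0, 1] intensity
  scale, added after truth is recorded. One seeded generator drives all
  randomness; identical seeds give bit-identical outputs.
- Default calibration 1.625 μm/px (a typical ×4 objective with a 6.5-μm
  camera pixel) at 8 min/frame; default capture 31 frames at 50%
  confluency with zero drift, matching the stationary-growth regime the
  start condition demands; default speed 45 μm/h, mid-range of a healthy
  cohort.

What the generator does **not** emulate: cell division and death,
colony merging/splitting, biomechanical interactions, photometric
artifacts (vignetting, debris, illumination drift), and non-rigid
intra-colony deformation. Passing tests therefore demonstrate that the
measurement chain is correct and accurate for textured regions in
collective motion — not that segmentation or flow are robust to every
pathology of real micrographs.

`make_cohort` attaches synthetic doubling times via a user-supplied
monotone speed→PDT link plus Gaussian noise, so cohort-level statistics
can be validated against the correlation computed on ground-truth pairs.

## Problem sizes used in validation

Tests and the acceptance script run the generator at 96–256 px frames
with 2–10 frames per capture and 32-sample cohorts — small enough to
validate every claim quickly while keeping the displacement-per-frame
(1–5 px) and confluency in the regime of the native protocol. The
segmentation accuracy criterion is evaluated at 256×256 across 30–90%
confluency; end-to-end speed recovery at 15–60 μm/h (1.2–4.9 px/frame
at the default calibration) with 5 independent seeds.

## Known limitations

- The Chan–Vese energy is non-convex; the data-driven initialization
  finds the colony-scale basin reliably on edge-density images but, like
  any level-set method, offers no global-optimality guarantee.
- The ~2 px segmentation halo biases growth upward slightly at low
  resolution (≈+1 point at 50% confluency, 256×256).
- The flow scheme assumes locally smooth displacement fields; motions
  larger than the pyramid can absorb (here ≳8 px/frame at default
  settings) underestimate.
- MMS is a spatial mean: it does not decompose motion per colony, nor
  separate advection from boundary growth.
- The 40 μm/h screening threshold is an empirical property of one
  culture system and transfers to no other without re-derivation.
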