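# Methods

This note documents the models, parameter choices and numerical decisions
behind `actintrace`, and what the synthetic test material does and does not
establish about behaviour on real micrographs.

## Source model and decomposition

A micrograph is modelled as `f = u_f + v_a + eta`: filamentous content,
smooth artifact content, additive Gaussian noise. The two components are
estimated by morphological component analysis — each content type is sparse
in its own dictionary and non-sparse in the other's — solved by
block-coordinate iterative thresholding: at every iteration each component
is re-synthesized from the thresholded analysis coefficients of its
marginal residual (`f` minus the other component).

**Dictionaries.** The fibers dictionary is a directional multiscale
Parseval frame built in the Fourier domain: Meyer-type radial windows split
the spectrum into a coarse low-pass plus dyadic rings (default 4 scales),
and each ring is multiplied by smooth angular wedges (default 8 per ring,
orientation period 180°) whose squares sum to one. The atoms are elongated
and orientation-selective, so quasi-straight filaments produce few large
coefficients — the defining property of curvelet-type systems. Windows are
explicitly symmetrized on the Nyquist row/column so that all coefficient
bands are real for real input; symmetrizing the squared windows preserves
the partition of unity, giving reconstruction to machine precision. The
artifacts dictionary is the undecimated (stationary) wavelet transform,
`db4` at 4 levels, energy-normalized; images are symmetrically padded to a
multiple of `2^levels` and cropped after synthesis, keeping the operator
pair exactly linear and invertible. Both dictionaries satisfy a round-trip
relative error ≤ 1e−6 (measured ~1e−16) and analysis linearity.

**Thresholds.** The global threshold is `γ = k·σ̂`, where `σ̂` is the MAD of
the input's finest `db1` diagonal band divided by 0.6745, and `k` falls
linearly from 30 to 3 over the iterations (default 100). Each coefficient
band is thresholded at `γ` times its white-noise gain (the standard
deviation the band would exhibit under unit white noise; computed exactly
from the frame windows for the directional frame, and empirically from a
fixed-seed noise image for the UDWT), so all bands are cut at equal
statistical significance. Hard thresholding (`p = 0`) is the default; soft
thresholding (`p = 1`) is available.

**Total-variation correction.** The objective's `δ`-weighted TV-style term
is implemented as a per-iteration soft-thresholding of the component's
level-1 undecimated Haar detail coefficients at `δ·σ̂` (`δ = 3` default) —
the light-weight TV surrogate customary in iterative-thresholding
separators. It is applied to the artifacts component by default
(`tv_target="artifacts"`), with a switch to apply it to the fibers/cartoon
component instead, since the separation literature is split on which
component the penalty should constrain.

**Noise estimate.** The reported noise level is the MAD estimator on the
finest wavelet band of the residual `f − u_f − v_a`. On the default
synthetic scenes the estimate comes out near 0.55× the injected σ: the two
redundant dictionaries together absorb part of the noise as γ approaches
its floor of 3σ̂. The estimate is well within a factor of two, stable
across seeds, and scale-equivariant.

## Enhancement chain

`u_E = directional_gaussian(|laplace(gaussian(u_f, σ=1))·β|, σ_dg=10)`,
rescaled to [0, 1].

- The 3×3 Laplace kernel is `β·[[0,−1,0],[−1,c,−1],[0,−1,0]]` with β = 10.
  The default center `c = −4` makes the kernel a negative smoother; a
  magnitude post-step (default on) recovers a positive ridge map for
  non-negative input. The conventional sharpening alternatives (`c = +4`
  Laplacian or `c = +5` unsharp) are available via `laplace_center` /
  `laplace_magnitude`; measured on the synthetic scenes they trade a little
  sensitivity for a little specificity and are not decisive either way.
- The directional filter bank uses anisotropic Gaussians with long-axis
  σ_dg = 10 and short-axis σ fixed at 1 px (preserving filament width while
  elongating support along the fiber), at 12 evenly spaced orientations,
  taking the per-pixel maximum. The nominal support is r = 2⌈3σ_dg⌉; the
  kernel is sampled at the r + 1 integer offsets spanning that support so
  it has an exact center pixel — an even-sized sample grid would shift
  every response by half a pixel and break 90°-rotation consistency
  (verified to hold within 5% relative L2, the limit set by orientation
  discretization).
- Rescaling `u_E` to [0, 1] makes the downstream threshold `b` scale-free:
  the chain's practical effect on faint or defocused fibers is contrast
  normalization.

## Line response and binarization

`R(x, y; θ, s, W)` is the mean of `u_E` over a length-`s` line element at
angle θ centered on the pixel, minus the mean over the `(2W+1)×(2W+1)`
window; line samples are integer offsets obtained by rounding positions
`j − (s−1)/2` along the direction half-up, and off-image samples use
mirror padding. Orientations are 0–180° in 15° steps (12 orientations);
`W = 4` by default. The multi-scale field averages the per-scale maxima
over θ for `s = 1..W` and adds the pixel's own intensity as the `(W+1)`-th
term, matching the `1/(W+1)` normalization; the pixel term can be
disabled. Raw means are used without local standardization. The
vectorized field agrees with a per-pixel nested-loop evaluation to
≤ 1e−10 everywhere (the tests sweep every pixel of random images).

Negative responses carry no line evidence, so the field is clipped at zero
before division by its maximum.

**Adaptive threshold.** The local intensity estimate is a 15×15 median
filter of `u_G`. Two readings of "retain a percentage b of the estimated
threshold" are implemented: `mode="fraction"` (foreground iff
`u_G > b·median`) and `mode="excess"` (foreground iff `u_G > median + b`
on the unit response scale). The fraction rule cannot reject homogeneous
positive background — any pixel exceeds a tenth of its own neighborhood
median — and on pipeline output it labels most of the image foreground;
the excess rule reproduces the sparse network masks the detector is meant
to produce, so it is the default, with b = 0.1. Both are monotone (smaller
`b` retains more pixels). Foreground components smaller than 5 px are
removed; strict inequality resolves the constant-image edge case.

## Fiber extraction

The mask is thinned to a 1-px skeleton (`skimage.morphology.skeletonize`).
Pixels with ≥ 3 skeleton neighbours are junctions; they terminate chains
and are attached to the first-traced adjacent chain in scan order, so every
skeleton pixel belongs to exactly one chain. Chains are traced from their
endpoints (cycles from their scan-order first pixel) with deterministic
tie-breaks.

Segments are grown greedily along each chain under a total-least-squares
line fit — perpendicular residuals, orientation-unbiased — closing when the
perpendicular RMS exceeds 1 px and discarding segments whose endpoint
distance is below `L = 30` px. Orientation is the principal axis of the
segment's pixels, in degrees on [0, 180) from the image horizontal.

Merging sweeps `ξ = 0..T_θ` (default `T_θ = 2°`); at each ξ, a single pass
merges segment `i` into the first later segment `k` with circular
orientation difference ≤ ξ and an endpoint of one chain within
`overlap_tol_px = 2` of the other chain. The merged orientation is the
length-weighted mean (with the 0/180 wraparound unwrapped before
averaging); pixels beyond the intersection point of the two fitted lines
are discarded, with the midpoint of the closest endpoint pair substituted
when the lines are within 0.5° of parallel. The merge is idempotent and
the fiber count is non-increasing in `T_θ` on the fixtures tested.

## Metrics

Confusion counts default to strict pixelwise comparison (`match_tol_px=0`);
a tolerant mode counts a predicted pixel within `match_tol_px` of any truth
pixel as TP (and symmetrically for misses), because rasterized filament
masks carry an intrinsic boundary ambiguity (below). Undefined ratios are
returned as NaN with an explicit warning, never as silent zeros.
Orientation statistics are linear mean and population (divide-by-n)
variance of θ on [0, 180), optionally length-weighted; axial circular
alternatives are provided but non-default, matching the common linear
reporting convention for fiber alignment.

## Synthetic scenes: what they emulate, and what they do not

Scenes compose anti-aliased quasi-straight strokes (flat intensity across
the width, one-pixel edge ramp; widths 1–8 px, lengths ≥ 30 px, default
60–120 px, intensities 0.6–1.0), isotropic Gaussian blobs (σ 5–20 px,
centers kept a blob-scale away from each other and from the border so no
thresholded blob forms a ridge), and i.i.d. Gaussian noise (σ = 0.04
default), clipped to [0, 1] after summation (documented as lossy). An
optional global Gaussian blur of the truth image emulates out-of-plane
defocus. Not emulated: a physical microscope PSF, photobleaching,
curvilinear (strongly bent) fibers, 3-D structure, or spatially
correlated noise — conclusions from passing tests transfer to real
micrographs only to the extent these factors are secondary.

Default evaluation scenes are 256×256 with 12 fibers (the examples and
acceptance computations use 256–384 px fields); these sizes keep the full
study reproducible in minutes on one CPU while matching the fiber density
of the imagery the method targets.

**Boundary ambiguity and scoring.** The truth mask is the set of pixels
within `width/2` of the centerline, while the rendered stroke extends half
a pixel further (the anti-aliasing ramp); any detector that reproduces the
drawn stroke therefore incurs a ~1-px false-positive ring at strict
scoring, and the enhancement chain's smoothing widens ridges by another
pixel or so. Pipeline-level sensitivity/specificity is accordingly scored
with a 1-px match tolerance, under which the framework operates at
Sn ≈ 0.94–0.96 and Sp ≈ 0.996 on the default scenes (strict-pixel values,
also reported by the acceptance script, run ≈ 0.84–0.89 / 0.985). The
high-sensitivity, near-unit-specificity regime — and the tendency of
errors toward slightly elongated fibers — matches the method's intended
operating point.

Fiber-level recovery is checked on well-separated straight fibers of
width 2–4 px (skeletonization retracts chain ends by roughly half the
stroke width, so very wide strokes would conflate end-retraction with
extraction error): ≥ 80% of fibers are recovered one-to-one with
orientation error ≤ 2° and length error ≤ 15% (measured: 100%, ~0.05°,
~1%).

## Known limitations

- The decomposition's noise-level estimate is biased low (≈ 0.5–0.6× the
  injected σ) because both redundant dictionaries absorb noise near the
  final threshold; relative comparisons between images remain valid.
- The merging sweep is single-pass per tolerance step as specified; a
  pathological chain of pairwise-mergeable segments may need a second
  invocation to reach its fixed point, though idempotence holds on all
  tested configurations.
- The fraction-mode adaptive threshold is provided for completeness but is
  not usable on images whose background response is positive (see above).
- Junction handling assigns each junction pixel to one chain; heavily
  overlapping networks can fragment into more segments than visually
  apparent fibers, which the merging stage only partly undoes.
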