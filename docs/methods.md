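# Methods

## The localization model

The method assumes a roughly horizontal finger, fingertip to the right,
rotated less than 30°, imaged in NIR transillumination so the finger band is
brighter than the background. Under these assumptions the finger silhouette
contributes exactly two horizontal-like edges — the upper and lower
boundaries — and those edge pixels occupy the extreme right tail of the
image's gradient population. Treating that population as approximately
normal motivates thresholding the horizontal Kirsch gradient at μ+kσ:
the retained fraction of an ideal normal field is 1−Φ(k), i.e. 2.28% at
k = 2, 15.87% at k = 1, 30.85% at k = 0.5. The three-level schedule
(2, 1, 0.5) trades false edges against completeness: a clean image needs
only the strict cut, an unevenly lit one progressively looser ones.

Thresholding is applied per image part (upper-left/right, lower-left/right)
with statistics recomputed from that part's own gradient values, because
uneven illumination makes a single global threshold wrong somewhere. Each
part accepts the first level whose longest 8-connected component spans at
least L columns; L defaults to half the part's width and may be configured
down to one third. Component "length" is *column span*, not pixel count —
the quantity that matters for a boundary line — and 8-connectivity is used
because a slanted boundary steps diagonally.

## Numerical and convention choices

- **Crop/resize arithmetic.** The margin crop keeps one pixel of the far
  boundary (retained extent = original − margins + 1) and the bicubic
  resize rounds output dimensions up (`ceil`). This is the unique pair of
  conventions under which all four dataset presets reproduce their
  published candidate sizes exactly (e.g. ZSC-FV:
  ceil((384−40+1)/2) × ceil((512−40+1)/2) = 173 × 237).
- **Bilateral filter** defaults: radius 4 (9×9 window), σ_spatial = 3 px,
  σ_range = 30 gray levels — conventional edge-preserving settings for
  8-bit images; all overridable. Border handling is replicate padding. The
  implementation is the literal normalized spatial×range Gaussian sum and
  is tested against a nested-loop evaluation of the definition.
- **Bicubic kernel**: Keys convolution kernel with a = −0.5, separable,
  replicate edges, pixel-center alignment, per-pixel weight normalization.
- **Kirsch operator**: correlation (no kernel flip), replicate padding so
  the gradient covers the full image, responses kept signed — clamping or
  absolute values would destroy the normal-like shape of the population
  that the μ+kσ schedule relies on.
- **Statistics**: population (divide-by-N) standard deviation; the
  threshold is a descriptive cut of the whole pixel population, not an
  estimator. The binarization is strict (>); a σ = 0 field yields an empty
  mask (a constant gradient has no edges).
- **Trace extraction**: a component collapses to one row per column as the
  rounded mean row of its pixels in that column; an exact .5 rounds toward
  the part's outer border. Gaps between the two same-side parts are filled
  by linear interpolation, ends by constant continuation. If one part of a
  side fails the whole schedule, the other part's trace extends across it;
  only a side with both parts failed raises an error.
- **ROI band**: exclusive of the boundary rows. The normalized ROI is the
  per-column band inside its bounding box, resized to 96×192 by default
  (the matching size is a free choice); an optional rectangle mode
  (rows max(upper)+1 … min(lower)−1) exists for matchers that need
  straight edges.
- **Tie-breaks** in component selection: widest column span, then more
  pixels, then higher topmost row — fixed so the pipeline is deterministic;
  identical input yields a bit-identical result.

## The phantom generator

`synthetic.PhantomSpec` renders what the assumptions describe: a bright
band (default 170 on background 40, 160×220 px, boundaries at rows 32 and
128) with a soft transition skirt (width 2×0.75 px outside each boundary,
saturating half a pixel inside, so noise-free interiors are exactly
two-level), optional slant up to tan 30°, shallow dark vein strokes
(5–10% of the band contrast, 2–3 px wide — subtle, as NIR veins are, so
they exercise false-edge robustness without rivalling the silhouette),
a smooth multiplicative illumination field, additive Gaussian noise
(σ = 3) and optional high-edge-density clutter patches outside the band.
All randomness flows from one integer seed through a single generator.

Degradation (`degrade_quadrant`) multiplies the band-background step around
one quadrant's boundary line by a dim factor over the outer 60% of that
part's columns, raised-cosine feathered in both directions (the row feather
reaches 34 px so its rejoin gradient stays below the σ cut). This
reproduces the failure mode the dynamic threshold exists for: the remaining
strong segment is shorter than L, forcing escalation, and the looser cut
recovers the weakened segment. A *uniform* dim of a whole quadrant would
test nothing — the μ+kσ binarization is invariant under scaling all of a
part's values — and dimming a rectangular block introduces spurious seam
edges; the localized, feathered dim avoids both.

The batch generator's class factors were calibrated once against the
default contrast and noise floor and then frozen: dim 0.21 lands the
weakened segment between the part's σ and 2σ cuts (class *medium*), dim
0.12 below the σ cut but usually above 0.5σ (class *poor*; an outright
failure also labels poor). Poor phantoms dim at most one part per side so
every boundary remains assemblable.

What the phantoms do **not** model: real sensor optics (scatter, blooming,
vignetting), finger texture and knuckle shadows, non-Gaussian noise, and
finger deformation. Passing the phantom batches therefore shows the
algorithm implements its contract — accurate boundaries where the
construction says they are, escalation exactly where contrast was removed —
not that any particular real dataset would yield given quality
percentages, which depend on the sensors.

## Problem sizes

The seeded test batches use 50 phantoms per condition at 160×220 px, and
oracle-equivalence checks run on images up to 32×32, sizes at which the
brute-force references are exact and fast; the analytic checks are
closed-form. The empirical tail check uses a 1000×1000 standard-normal
field, large enough that the three-binomial-standard-error band is ±0.045
percentage points at k = 2.

## Known limitations

- A finger rotated more than ~30° violates the horizontal-edge assumption
  and the horizontal masks stop seeing the boundary.
- The method finds only upper/lower boundaries; no fingertip or finger-tail
  trimming is attempted.
- On images whose background contains long horizontal structures of
  near-boundary strength, the longest-component heuristic can lock onto
  them; the escalating threshold mitigates but cannot exclude this.
- Whether real acquisition pipelines recompute μ, σ per part or reuse
  global statistics is a modelling choice; this package recomputes per part
  (each part "adopts its own threshold"), and `detect_quadrant_edge`
  accepts precomputed statistics for the global variant.
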