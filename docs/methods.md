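# Methods

`veinseg` measures leaf vein density — total vein length per unit leaf area
(mm·mm⁻²) — from calibrated RGB micrographs of chemically cleared, stained
leaves, using object-based image analysis (OBIA): the image is first
partitioned into homogeneous *objects*, and classification rules operate on
object features rather than on pixels. This note records the models,
parameter choices and numerical decisions, and what the synthetic benchmark
does and does not demonstrate.

## Calibration and preprocessing

An image is tied to a physical field of view (default 2.2013 × 1.6468 mm,
a compound microscope at 40×); the pixel size is derived from the field
width, assuming square pixels (a > 2 % width/height disagreement raises a
calibration warning and the width-derived value is used). Intensities are
non-negative integers of any bit depth.

Preprocessing is a 1 % linear contrast stretch per band: values at or below
the 1 % nearest-rank quantile map to 0, at or above the 99 % quantile to
255, linearly in between with integer rounding. Nearest-rank quantiles on
the sorted pixel multiset make the stretch platform-independent; constant
bands are passed through with a warning. All classification thresholds are
applied to the stretched image: the stretch is what makes one threshold set
serve micrographs of varying exposure, and the published brightness window
(230–280, exceeding the 8-bit maximum) only makes sense on a normalised
scale measured after such a stretch.

## Multiresolution segmentation

Objects are built by bottom-up region merging. The cost of fusing objects
*a*, *b* is the increase in weighted heterogeneity

    f = (1 − w_shape)·Δh_color + w_shape·Δh_shape
    Δh_color  = Σ_b w_b (n_ab σ_ab − n_a σ_a − n_b σ_b)
    Δh_shape  = w_cmpct·Δh_cmpct + (1 − w_cmpct)·Δh_smooth
    h_cmpct = l/√n,  h_smooth = l/p_bbox,  Δh_* = n_ab h_ab − n_a h_a − n_b h_b

with n the pixel count, σ_b the population standard deviation of band b, l
the border length in pixel edges and p_bbox the bounding-box perimeter. A
merge is admissible while f < scale². Defaults are scale 250, shape weight
0.7, compactness weight 0.3 and equal band weights — the recommended
universal values for this imagery.

The engine starts from single-pixel objects and proceeds in *rounds*: in
each round every mutually best-fitting admissible pair (each object is the
other's cheapest neighbour; ties broken by the lowest object id in raster
order) is merged simultaneously, with all costs evaluated on the state at
the start of the round. Rounds repeat until no admissible mutual pair
remains; at termination every surviving adjacency necessarily costs
≥ scale². The simultaneous-matching formulation allows the whole round to
be computed vectorised; it is deterministic for a fixed input. Object
statistics are carried incrementally as integer-exact sums and
sums-of-squares (border length via shared-edge counts, bounding boxes by
union), so recomputing any statistic from the raw pixels reproduces the
carried value; an audit mode records every accepted merge for exactly this
cross-check. Objects are 4-connected throughout; segmentation can be
confined to a mask (pixels outside carry label −1).

A consequence of the cost structure worth knowing: at scale 250, a
background pocket fully enclosed by veins, or an isolated bright fragment
smaller than roughly a thousand pixels, *cannot* survive as its own object
— some adjacent merge always stays below the threshold — so severed vein
fragments below that size are unavoidably lost to the background class (and
enclosed background pockets are absorbed into vein objects). This is a
property of the published parameter set, not of the implementation.

## Object features and the rule cascade

- **Brightness**: arithmetic mean of the three per-band object means.
- **Spectral**: per-band means; the red band is the discriminative one.
- **Density** (geometric): √n / (1 + √(VarX + VarY)) with population
  variances of the pixel coordinates. A single pixel scores 1, thin
  curvilinear objects score below ~1.5, large filled blobs approach
  √6 ≈ 2.45; the natural break near 2 separates vein-like from
  stomata-like shapes. Note the break is size-dependent: filled disks
  below ~12 px diameter still score < 2.
- **Length/width**: with λ₁ ≥ λ₂ the eigenvalues of the pixel-coordinate
  covariance, the aspect ratio is γ = √(λ₁/λ₂) (eigenvalues are variances,
  so the linear ratio is the root of their ratio), length = √(n·γ),
  width = n/length, γ capped at n so width ≥ 1; collinear sets get
  width 1, length n.

Classification is a fixed three-stage cascade, all bounds inclusive:
brightness ∈ [230, 280] → vein candidate; red mean ≥ 180 (an upper red
bound of 230 exists but is disabled by default — the operative rule in
practice is "180 or more"); candidates are then merged into 4-connected
components and each component with density ≤ 2 becomes vein. Later stages
only demote, so the vein pixel set shrinks monotonically through the
cascade.

## Reconnection of interrupted veins

Trichome occlusions cut veins into fragments. Reconnection runs in two
steps (the "circulating growth" scheme):

1. **Straightening.** The vein pixels are re-segmented with a decreasing
   scale ladder fg = 150·0.9ᵏ while fg > 10 (exactly 26 passes), shape
   weight 0.7, compactness weight 0.9; every object with density < 2 is
   frozen as a segment, leftovers are frozen at exit. On thin networks the
   density bound is satisfied immediately, so segments are typically whole
   connected fragments; this is why the growth step below measures
   direction *locally* rather than from the segment's global axis.
2. **Growth.** The background is treated as single-pixel fusion candidates.
   For 8 cycles, each segment fuses adjacent background pixels that
   increase its principal length (target weight 1, seed weight −1,
   candidate weight 0; accept iff TL − SL > 0), with three numerical
   refinements: (a) lengths are evaluated on the *local end* — the segment
   pixels within a square window of radius 12 px around the candidate —
   since a whole branched fragment has no meaningful global direction;
   (b) the trivial √n̄ inflation is removed: adding any pixel raises
   √(n·γ) by ≈ SL/2n even when elongation worsens, so a fusion must beat
   SL·√((n+1)/n) by a noise margin (0.05 px) that jagged-boundary
   candidates do not reach; (c) growth advances at most two pixel rings per
   segment end per cycle. Fronts therefore advance along the local vein
   axis, across gaps, and stop against other vein pixels.
3. **Rollback.** After the last cycle, a grown pixel is kept only if it
   lies on a shortest path, through grown pixels, between two distinct
   pre-growth vein fragments, the path is no longer than 14 px (an
   occlusion-scale bound; anything longer is a spurious long-range join),
   and the straight chord between the two contacts is preferred whenever
   the grown field covers it. Everything else — in particular exploratory
   growth at free vein tips — is rolled back, so tips end where they ended
   before growth and every closed gap keeps a tight bridge.

The window radius, noise margin, ring cap and bridge-length bound are
configurable (`ReconnectionConfig`); the defaults were chosen from the
geometry of the target imagery (vein widths 3–7 px, occlusion spans
≤ ~13 px) and are not sensitive within factor-of-two changes, except that
the bridge-length bound must exceed the largest occlusion span to be
closable and stay below the smallest inter-vein spacing.

## Density measurement and accuracy statistics

The vein mask is the union of vein-labelled objects; the skeleton is its
medial axis. Length is the step-sum over skeleton adjacencies (1 px
orthogonal, √2 px diagonal, skipping diagonals already covered by an
orthogonal corner), plus, by default, the local medial radius at every
skeleton endpoint: thinning erodes roughly half a stroke width at each free
vein ending, and the endpoint correction removes that bias (measured on
ground-truth scenes it shrinks the systematic length error from about −3 %
to within ±1 %). The raw uncorrected sum is available
(`tip_correction=False`). Density = length / (width_px·height_px·pixel²).

Batch accuracy against reference densities follows the printed convention
of the method: R = (1/n)Σ(P1ᵢ − P0ᵢ) — the *signed* mean error, kept
exactly as printed even though opposite errors cancel — and
P′ = (P̄1 − R)/P̄1 × 100 %. An RMSE variant of R is available behind a
flag, and tolerance-based pixel precision/recall/F1 (true positive within
2 px Chebyshev) complements the cancellable signed statistic.

## Synthetic scenes

Real cleared-leaf micrographs for this imagery are not publicly deposited,
so every stage is validated on a generator with exact ground truth. A scene
is a pure function of its configuration and seed.

**Geometry.** Netted mode draws a midrib bowing across the field, ~13
secondaries branching at 28–42°, and ~30 short tertiaries, as gently
curving random-walk paths; parallel mode draws near-parallel longitudinal
veins. Strokes are rasterised at 7/5/3 px width (≈ 30/21/13 µm at the
default calibration). The network is tree-structured with freely ending
veinlets: paths stop before entering a 20 px exclusion zone around other
veins (areole-scale spacing), retract one step when so blocked, never
re-enter their parent's zone after leaving it, and keep their free ends
≥ 18 px from other free ends. Loops are deliberately not modelled: the
gap-closure audit is a connected-component test, which a reticulate mesh
would trivially satisfy around any cut.

**Intensities.** Per pixel a brightness B and red value R are drawn and
green/blue set to (3B − R)/2 ∓ a small split term, so brightness is exact
before noise. Veins: B ~ 245 ± 3, R ~ 205 ± 6 (green/blue then exceed 255,
hence 16-bit rasters meant to be stretched). Background: B ~ 120 ± 20,
R ~ 140 ± 15, with a spatially correlated component (Gaussian field,
correlation length ≈ one mesophyll cell) shared between bands — stained
mesophyll is patchy, not white noise, and the patchiness is what keeps
background objects moderately sized during segmentation. Compact bright
clutter blobs (stomata/guard cells, brightness 200 ± 8 by default, the vein
distribution in "hard mode") and Gaussian pixel noise complete the scene.
The vein spreads are deliberately tight: the stretch is scale-normalising,
so the stretched vein brightness depends only on the spread-to-contrast
ratio, and the generator must keep ≥ 99 % of vein pixels inside the rule
bounds *on the stretched scale* for the default thresholds to be the
correct operating point.

**Occlusions.** Gaps are cut on the midrib/secondaries (a trichome is an
order of magnitude wider than the finest veinlets, so only there is an
interruption both observable and reconnectable), removing 2–6 centreline
pixels plus the stroke cross-section. A site is accepted only if the cut
truly disconnects the network and every flank keeps ≥ 1200 rendered pixels
— below ~1100 px a severed fragment is necessarily absorbed by the
background during segmentation (see above), leaving nothing to reconnect.
The truth retains the full network; each gap records its flanking anchor
pixels for the closure audit.

**What passing does and does not show.** The synthetic scenes have crisp
vein edges, no uneven clearing or staining gradients, no out-of-focus blur
and no true reticulation. Passing demonstrates that the pipeline's
machinery — segmentation, thresholds, reconnection, calibrated length
measurement — is implemented correctly and recovers known truth under the
stated imaging model; it does not certify accuracy figures on real
micrographs of any particular species.

## Problem sizes and determinism

Default scenes are 512 × 383 px (the full reference field at ~4.3 µm/px);
benchmark batches use 30 scenes for density recovery and 30 five-gap scenes
for closure. A single scene runs the full pipeline in seconds on one core.
All randomness flows from explicit seeds; re-running any pipeline or
generator call with the same inputs is bit-identical.

## Known limitations

- Vein-order classification, areole statistics and loop closure are out of
  scope.
- The density feature's threshold of 2 does not reject small compact blobs
  (< ~12 px diameter); such clutter must fail the brightness or spectral
  rule instead.
- The signed-error accuracy statistic can report 100 % despite per-sample
  errors; use the pixel metrics alongside it.
- Enclosed background pockets and sub-threshold fragments are
  misassigned by any implementation of the scale-250 merge criterion; on
  real imagery this surfaces as slight brightness dilution of vein objects
  near junctions.
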