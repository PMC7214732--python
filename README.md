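# veinseg

Object-based extraction of leaf vein networks and measurement of vein
density from calibrated micrographs of chemically cleared, stained leaves.

Vein density — the total vein length per unit leaf area, in mm·mm⁻² — is a
key functional trait linking leaf hydraulics, photosynthetic capacity and
climate adaptation, but measuring it by manually tracing veins in a
micrograph is slow and error-prone. `veinseg` automates the measurement
with the object-based image analysis (OBIA) approach familiar from remote
sensing, applied to microscope fields of view (default 2.2013 × 1.6468 mm
at 40×):

1. **Preprocessing** — a 1 % linear contrast stretch per band normalises
   exposure so one threshold set serves a whole batch.
2. **Multiresolution segmentation** — bottom-up region merging that fuses
   objects *a*, *b* while the heterogeneity increase
   `f = (1−w_shape)·Δh_color + w_shape·Δh_shape` stays below `scale²`,
   with `Δh_color = Σ_b w_b(n_ab σ_ab − n_a σ_a − n_b σ_b)` and the shape
   term mixing compactness `l/√n` and smoothness `l/p_bbox`. Defaults:
   scale 250, shape 0.7, compactness 0.3.
3. **Rule-based classification** — a three-stage knowledge base labels
   objects as vein or background: brightness ∈ [230, 280] → spectral red
   mean ≥ 180 → merged components with density feature
   `√n/(1+√(VarX+VarY)) ≤ 2` (small for curvilinear objects, ≈ √6 for
   blobs).
4. **Reconnection** — veins interrupted by trichome occlusions are spliced
   by the circulating-growth method: decompose into straight segments with
   a decreasing scale ladder (150 × 0.9ᵏ > 10, 26 passes), then grow each
   segment end across background for 8 cycles under the length-fitting
   rule TL − SL > 0 (target weight 1, seed −1, candidate 0); growth that
   fails to splice two fragments is rolled back.
5. **Density** — the medial-axis skeleton of the vein mask is step-summed
   (1 px orthogonal, √2 diagonal, endpoint-radius tip correction) and
   converted with the physical pixel size.

Batch accuracy against reference measurements uses
`R = (1/n)Σ(P1ᵢ−P0ᵢ)` and `P′ = (P̄1 − R)/P̄1 × 100 %`, plus
tolerance-based pixel precision/recall/F1.

A synthetic-scene generator (`veinseg.synth`) renders calibrated
cleared-leaf micrographs — netted or parallel venation, textured mesophyll,
stomatal clutter, optional occlusion gaps — with exact ground truth, so
every stage is testable without real micrographs.

## Worked example

```python
import veinseg as vs

scene = vs.generate(vs.SceneConfig(seed=42))          # known ground truth
veinmap, report = vs.run_single(scene.image)          # full pipeline

print(f"true density      {scene.truth_density_mm_per_mm2:.3f} mm/mm^2")
print(f"extracted density {veinmap.density_mm_per_mm2:.3f} mm/mm^2")
print(f"vein length       {veinmap.total_length_mm:.3f} mm over "
      f"{veinmap.area_mm2:.3f} mm^2")
```

prints

```
true density      4.031 mm/mm^2
extracted density 3.960 mm/mm^2
vein length       14.355 mm over 3.625 mm^2
```

i.e. the pipeline recovers the known vein density of this scene to 1.8 %.
The `examples/` directory walks through each capability (scene generation,
segmentation + classification, gap reconnection, batch accuracy); each
script prints the numbers it computes and what they mean. A thin CLI mirrors
the library:

```bash
veinseg synth --seed 1 --out scene/          # write image.tif + truth.json
veinseg run scene/image.tif --out result/    # mask, skeleton, density
veinseg batch scenes/ --out report.csv       # one CSV row per image
```

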