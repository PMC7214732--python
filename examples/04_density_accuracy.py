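"""Measure vein density end to end and score it against ground truth.

Runs the full pipeline on a small batch of synthetic micrographs and
evaluates the extraction accuracy statistic
P' = (P1_bar - R) / P1_bar * 100 with R the mean signed density error.
"""

import veinseg as vs

truth, extracted = [], []
for seed in (1, 2, 3, 4, 5):
    scene = vs.generate(vs.SceneConfig(seed=seed))
    veinmap, report = vs.run_single(scene.image)
    truth.append(scene.truth_density_mm_per_mm2)
    extracted.append(veinmap.density_mm_per_mm2)
    print(f"seed {seed}: truth {truth[-1]:.3f}  extracted {extracted[-1]:.3f} mm/mm^2")

rep = vs.accuracy(truth, extracted)
print(f"\nmean signed error R : {rep.R:+.4f} mm/mm^2")
print(f"extraction accuracy : {rep.P_prime:.2f} %")
# P' close to 100 means the extracted densities track the true ones with
# negligible systematic bias; per-scene errors are within a few percent.
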