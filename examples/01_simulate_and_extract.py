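"""Simulate a hyperspectral seed scene, calibrate it, and extract ROIs.

Renders 50 elliptical seeds of four vigor classes on a 128x256x360 cube,
applies black/white reflectance calibration, segments the 635.77 nm band
and reports how many seeds were recovered and how well an affine-invariant
nearest-class-curve rule matches the ground truth.
"""

import numpy as np

from seedvigor import SceneSpec, make_class_spectra, render_scene, segment_scene
from seedvigor.synthetic import assign_nearest_class

models = make_class_spectra(rng_seed=42)
scene = render_scene(SceneSpec(rng_seed=42), models)
cube = scene.calibrated()
rois = segment_scene(cube)

truth = scene.truth.set_index("seed_id")
hits = 0
for roi in rois:
    ids = scene.label_map[roi.mask]
    true_id = int(np.bincount(ids[ids > 0]).argmax())
    hits += assign_nearest_class(roi.mean_spectrum, models) == truth.loc[true_id, "vigor"]

print(f"planted seeds:    {len(truth)}")
print(f"extracted ROIs:   {len(rois)}")
print(f"mean ROI area:    {np.mean([r.area for r in rois]):.1f} px")
print(f"crop stack shape: {rois[0].crop.shape}")
print(f"nearest-curve label recovery: {hits}/{len(rois)}")
# Expected: all 50 seeds recovered; recovery ~100% at the default 1% noise.
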