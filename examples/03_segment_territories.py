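"""Threshold-based process-territory segmentation.

Somata are masked (dilated), the projection is binarized at an Otsu
threshold, and 8-connected components larger than 50 px become
"process territories" — each typically a primary process with its
branches.
"""

import numpy as np

from caltrack import (Roi, SimulationConfig, average_intensity_projection,
                      simulate, threshold_territories)

cfg = SimulationConfig(image_shape=(256, 256), n_frames=200, n_cells=4, seed=11)
stack, truth, _ = simulate(cfg)
projection = average_intensity_projection(stack)
somas = [Roi(id=name, kind="soma", mask=m, pixel_size_um=cfg.pixel_size_um)
         for name, m in truth.soma_masks.items()]

territories = threshold_territories(projection, somas,
                                    pixel_size_um=cfg.pixel_size_um)
print(f"{len(territories)} territories, areas "
      f"{min(t.area_px for t in territories)}-"
      f"{max(t.area_px for t in territories)} px (all > 50 px)")

union = np.zeros(projection.shape, bool)
for t in territories:
    union |= t.mask
true_union = np.zeros(projection.shape, bool)
for m in truth.process_masks.values():
    true_union |= m
jac = (union & true_union).sum() / (union | true_union).sum()
print(f"Jaccard overlap with true process masks: {jac:.2f}")
# ~0.9+ at default noise: the threshold recovers the simulated arbors.
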