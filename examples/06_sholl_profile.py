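"""Sholl analysis: morphological complexity as circle intersections.

Concentric circles around the soma centre count the contiguous runs of
foreground pixels they cross; for a star cell with four straight rays,
every circle between soma edge and ray tip crosses exactly four.
"""

import numpy as np

from caltrack.motility import sholl_profile
from caltrack.validation import star_cell_mask

mask, center = star_cell_mask(n_rays=4, ray_len_px=80, soma_r_px=10)
profile = sholl_profile(mask, center, r_max_um=90, step_um=10,
                        pixel_size_um=1.0, cell_id="star")

for r, n in zip(profile.radii_um, profile.intersections):
    bar = "#" * int(n)
    print(f"r = {r:4.0f} um: {n} intersections {bar}")
# 1 inside the soma, 4 along the rays, 0 beyond the ray tips (80 um)
print("total crossings:", int(np.sum(profile.intersections)))
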