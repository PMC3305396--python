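"""Detect foci in one synthetic nucleus and compare against ground truth.

Renders a 22-slice, 14-bit field (0.07 um/pixel, 0.5 um z-step) containing
one nucleus with eight medium-sized foci (0.7 um FWHM), runs the full
filter chain and 3D reconstruction, and scores the result.
"""

import numpy as np

from autorif import FilterSettings, segment_nuclei
from autorif import synthetic_fixtures as synth
from autorif.pipeline import process_nucleus

shape = (22, 512, 512)
truth = synth.default_truth(
    8, seed=42, shape=shape, sigma_choices_xy_px=[synth.SIGMA_MEDIUM_PX]
)
nuclear, focus = synth.render_field(truth, shape)

regions = segment_nuclei(nuclear)
nucleus = regions[0]
print(f"nucleus: {nucleus.area_px} px, centroid {np.round(nucleus.centroid_xy, 1)}")

foci = process_nucleus(focus, nucleus, FilterSettings())
print(f"\ndetected {len(foci)} foci (ground truth: {len(truth.foci)})")
for f in foci:
    x, y, z = f.centroid_3d_um
    print(
        f"  focus {f.focus_id}: ({x:5.2f}, {y:5.2f}, {z:5.2f}) um, "
        f"d_eq={f.equivalent_diameter_um:.2f} um ({f.size_category}), "
        f"volume={f.volume_um3:.3f} um^3, {f.z_extent} slices"
    )

score = synth.score_against_truth(
    foci, truth, match_radius_um=1.0,
    detected_origin_px=(nucleus.bbox[1], nucleus.bbox[0]),
)
print(
    f"\nmatched {score['n_matched']}/{score['n_true']}, "
    f"3D localisation RMSE {score['localisation_rmse_um'] * 1000:.0f} nm"
)
# the centroid error is a small fraction of a pixel; every detected
# diameter falls in the 0.5-1.0 um bin matching the rendered 0.7 um FWHM
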