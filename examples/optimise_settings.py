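"""Batch optimisation of filter settings on a sample of nuclei.

Under-filtering shows up as salt-and-pepper noise: isolated 1-pixel
components in the binary masks.  A grid of candidate smoothing iterations
is scored on a seeded sample of nuclei; the recommendation is the lightest
setting whose salt-and-pepper score stays under the cap.
"""

import tempfile
from pathlib import Path

from autorif import RunConfig, optimise_batch
from autorif import synthetic_fixtures as synth

shape = (8, 224, 224)

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp) / "experiment"
    for i in range(2):
        truth = synth.default_truth(
            4, seed=61 + i, shape=shape,
            sigma_choices_xy_px=[synth.SIGMA_MEDIUM_PX],
        )
        # heavy read noise to make under-filtering visible
        truth.noise = synth.NoiseModel(gaussian_sd=60.0, background_level=400.0)
        synth.write_field(truth, root / f"field_{i:02d}", shape)

    config = RunConfig(input_root=root, output_dir=Path(tmp) / "opt", seed=1)
    report = optimise_batch(
        config,
        grid={"pre_iterations": [0, 1, 3, 5], "post_iterations": [3]},
        salt_pepper_cap=2.0,
    )
    cols = ["pre_iterations", "post_iterations", "salt_pepper_per_nucleus",
            "mean_focus_count", "count_drift_vs_lightest", "acceptable"]
    print(report[cols].round(2).to_string(index=False))
    best = report.iloc[0]
    print(
        f"\nrecommended: pre={best.pre_iterations} post={best.post_iterations} "
        f"(lightest acceptable setting that detects foci)"
    )
# rows are ranked: acceptable settings that actually detect foci first,
# then by total iterations — more pre-smoothing lowers the salt-and-pepper
# score at the cost of rounding focus outlines; with too little smoothing
# the noise swamps the histogram and detection collapses entirely
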