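"""Orientation analysis: aligned versus isotropic fiber populations.

Mirrors the flow-alignment contrast: a population aligned near 80 degrees
(the shear-flow direction) shows a single-mode normalized histogram and a
small orientation variance, while an isotropic population spreads over
the whole angular spectrum with a much larger variance.
"""

from actintrace import (
    MergeConfig,
    angular_distribution,
    extract_fibers,
    orientation_stats,
    random_scene,
)

aligned = random_scene(n_fibers=14, shape=(320, 320), seed=61,
                       angle_range=(78.0, 82.0), width_range=(2.0, 4.0),
                       min_separation=8.0, n_blobs=0, noise_sigma=0.0)
static = random_scene(n_fibers=14, shape=(320, 320), seed=62,
                      width_range=(2.0, 4.0), min_separation=8.0,
                      n_blobs=0, noise_sigma=0.0)

for name, scene in (("sheared (aligned ~80 deg)", aligned),
                    ("static (isotropic)", static)):
    fibers, _ = extract_fibers(scene.truth_mask, MergeConfig(T_theta=2))
    stats = orientation_stats(fibers)
    hist = angular_distribution(fibers, bin_width_deg=10.0)
    mode = hist.bin_edges[hist.normalized.argmax()]
    print(f"{name:28s} fibers={len(fibers):2d}  mean={stats.mean_deg:6.1f}  "
          f"variance={stats.variance_deg2:8.1f}  mode bin=[{mode:.0f},{mode + 10:.0f})")
# The variance ratio (isotropic >> aligned) is the quantitative signature
# of stress-fiber alignment under flow.
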