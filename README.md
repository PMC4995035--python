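# actintrace

Extraction and quantification of actin stress fibers from single-channel
fluorescence micrographs.

Actin stress fibers — bundles of actin filaments that form in response to
mechanical stimuli — appear in phalloidin-stained micrographs as bright,
quasi-straight curvilinear structures, often buried under out-of-focus
blur, staining debris and noise. `actintrace` implements a three-stage
analysis that turns such an image into a list of individual fibers, each
with position, orientation and length, plus the pixel-level evaluation
metrics and orientation statistics used to compare fiber populations
(e.g. cells grown under fluid shear stress versus static controls).

## Method

Given a micrograph `f` normalized to [0, 1], the image is modelled as

```
f = u_f + v_a + eta
```

with `u_f` the filamentous content, `v_a` smooth blob-like artifacts and
`eta` additive noise, and processed in three stages:

1. **Sparse decomposition.** `u_f` and `v_a` are estimated by two-dictionary
   morphological component analysis: block-coordinate iterative thresholding
   of the objective

   `min ||f − D_a λ_a − D_f λ_f||² + γ‖λ_a‖_p + γ‖λ_f‖_p + δ(∇λ_a + ‖λ_a‖₁)`

   with a directional multiscale tight frame (curvelet-type) as the fibers
   dictionary `D_f`, an undecimated wavelet transform as the artifacts
   dictionary `D_a`, hard thresholding (`p = 0`), `δ = 3`, and a threshold
   `γ` decremented linearly over 100 iterations. The residual `f − û` is the
   noise estimate, whose level is measured by the MAD of its finest wavelet
   band.

2. **Enhancement and line detection.** `u_f` is smoothed (Gaussian, σ = 1),
   sharpened with a scaled 3×3 Laplace kernel (β = 10) and reinforced by a
   bank of anisotropic directional Gaussians (σ_dg = 10, support
   r = 2⌈3σ_dg⌉, max over orientations), giving `u_E`. The multi-scale line
   response

   `u_G(x,y) = 1/(W+1) · Σ_{s=1..W} max_θ R(u_E; θ, s, W)`

   scores each pixel by how much brighter a length-`s` oriented line element
   through it is than its `(2W+1)×(2W+1)` window (`W = 4` is the expected
   fiber width). `u_G` is binarized by a Wellner-style adaptive threshold
   derived from a local median (`b = 0.1`), giving the network mask `u_B`.

3. **Fiber extraction.** `u_B` is thinned to a skeleton and traced into
   chains; total-least-squares fitting partitions chains into quasi-straight
   segments (perpendicular error ≤ 1 px, minimum length `L = 30`); a sweep
   over an increasing angle tolerance `ξ = 0..T_θ` merges overlapping,
   similarly oriented segments into individual fibers, with length-weighted
   orientation averaging.

Evaluation uses pixelwise accuracy, sensitivity `TP/(TP+FN)` and
specificity `TN/(TN+FP)` against ground truth, and fiber populations are
summarized by the normalized angular histogram and the mean/variance of
orientations.

Because no public micrographs accompany the method, the package includes a
first-class synthetic-scene generator (`actintrace.synthetic`) producing
ground-truthed networks of quasi-straight fibers (widths 1–8 px, lengths
≥ 30 px) over Gaussian-blob artifacts with σ = 0.04 noise, against which
every stage is tested.

## Worked example

```python
import numpy as np
from actintrace import (MCAConfig, curvelet_dictionary, udwt_dictionary,
                        mca_decompose, random_scene)

scene = random_scene(n_fibers=10, shape=(192, 192), seed=3)
result = mca_decompose(scene.composite, curvelet_dictionary(),
                       udwt_dictionary(), MCAConfig(n_iter=60))
corr = lambda a, b: np.corrcoef(a.ravel(), b.ravel())[0, 1]
print(f"corr(input,  truth fibers): {corr(scene.composite, scene.truth_image):.4f}")
print(f"corr(fibers, truth fibers): {corr(result.fibers, scene.truth_image):.4f}")
print(f"estimated noise sigma:      {result.estimated_noise_sigma:.4f}")
```

prints

```
corr(input,  truth fibers): 0.9878
corr(fibers, truth fibers): 0.9954
estimated noise sigma:      0.0230
```

— the separated fibers image correlates better with the ground-truth
filament image than the raw input does, and the residual carries the
injected noise (σ = 0.04) within a factor of two. The scripts under
`examples/` walk through each capability (scene simulation, decomposition,
enhancement + detection, fiber extraction, orientation analysis) and print
the numbers they compute. A thin CLI mirrors the library:

```
actintrace simulate -o scene --n-fibers 10 --seed 3
actintrace run scene/composite.tif -o out -W 4 -b 0.1 -L 30
```

which writes intermediate images (`u_f`, `u_E`, `u_G`, `u_B`), fiber and
segment tables, an orientation histogram, a color overlay and a JSON run
manifest to `out/`.

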