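"""Estimate the MST membership distribution of one synthetic image.

Full pipeline: frame removal, lesion masking, VB-GMM density fit on the
normal skin, Kullback-Leibler divergence against each of the ten Monk
Skin Tone reference densities, softmax membership scores.
"""

import json

import numpy as np

from mstai import EvaluationGrid, MaskProvider, SyntheticSpec, estimate_image, generate_image
from mstai.io import default_swatch_path, load_reference

# reference densities fitted from the shipped Monk palette (cached on disk)
reference = load_reference(default_swatch_path(), n_pixels=2000, seed=0)

# skin drawn around scale 6's swatch (160, 126, 86), with a second tone
swatch = np.array(json.loads(default_swatch_path().read_text())["scales"][5]["rgbs"][0], float)
spec = SyntheticSpec(
    frame_style="corner_circle_dark",
    frame_radius_fraction=0.85,
    lesion_present=True,
    lesion_center=(44, 44),
    lesion_axes=(6, 5),
    lesion_color_rgb=(50, 32, 28),
    skin_mixture=[
        (0.7, tuple(swatch), np.eye(3) * 36.0),
        (0.3, tuple(swatch + 12), np.eye(3) * 36.0),
    ],
    rng_seed=5,
)
image, _, lesion_truth = generate_image(spec)

result = estimate_image(
    image,
    reference,
    provider=MaskProvider.from_array(lesion_truth),
    grid=EvaluationGrid(64),
    seed=0,
)

mv = result.membership
print("scale :  " + "  ".join(f"{m:5d}" for m in range(1, 11)))
print("KLD   :  " + "  ".join(f"{d:5.1f}" for d in mv.divergences))
print("score :  " + "  ".join(f"{s:5.3f}" for s in mv.scores))
print(f"ranking (best to worst): {mv.ranking.tolist()}")
print(f"top-1 scale: {mv.top1}")
# Scores sum to 1; the smallest divergence (information lost when this
# image's skin density stands in for the scale) gets the largest score.
# Skin generated around scale 6 should rank scale 6 first.
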