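"""What the training-time lesion simulator produces.

Applies the concentric-disc lesion simulator (elastic-deformed discs,
Gaussian-blurred into soft weights, multiplicative darkening) to one
healthy phantom cross-section and prints the draw statistics.
"""

import numpy as np

from strokect.lesion_sim import LesionSimParams, simulate_lesion
from strokect.phantom import PhantomSpec, make_brain_phantom
from strokect.restoration_net import normalize_stack
from strokect.volume_io import split_hemispheres

spec = PhantomSpec(seed=0)
vol, truth = make_brain_phantom(spec)
pair = split_hemispheres(vol, truth.midline_column, (96, 64), 1)
healthy = normalize_stack(pair.contralateral.data)[16]

params = LesionSimParams()  # reference ranges at full scale
print("simulation parameter ranges:")
print(f"  outer radius   : {params.outer_radius_range} px")
print(f"  inner fraction : {params.inner_radius_fraction_range} of outer")
print(f"  lesion drop    : {params.lesion_intensity_drop_range}")
print(f"  core extra drop: {params.core_extra_drop_range}")
print(f"  blur sigma     : {params.blur_sigma_range} px, "
      f"elastic alpha={params.elastic_alpha} sigma={params.elastic_sigma}")

scaled = params.scaled(0.5)  # for the 96 x 64 demo slices
rng = np.random.default_rng(4)
lesioned, w_lesion, w_core = simulate_lesion(healthy, scaled, rng)

inside = w_lesion > 0.5
print()
print(f"lesion weight support : {inside.sum()} of {healthy.size} pixels")
if inside.any():
    drop = 1 - lesioned[inside].sum() / healthy[inside].sum()
    print(f"mean intensity drop inside lesion: {drop:.1%}")
print(f"darkening only: max(lesioned - healthy) = {(lesioned - healthy).max():.2e}")
print()
print("The pair (lesioned input, healthy target) is one training sample;")
print("the weight maps are the ground truth the simulator hands to tests.")
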