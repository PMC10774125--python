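"""SVD clutter filtering at the Doppler-ensemble level.

Power-Doppler images are formed from an ensemble of compounded frames after
removing the dominant singular components, which carry slowly varying tissue
signal; fluctuating blood signal survives in the residual.  Here 200 frames
are filtered discarding the first 30% (= 60) of components.  Note the
geometry matters: the blood region must span more slow-time components than
the clutter cutoff, which holds in real images where blood fills much of the
field of view.
"""

import numpy as np

from fusbmi import svd_clutter_filter

rng = np.random.default_rng(0)
H, W, N = 24, 30, 200

tissue = rng.uniform(10, 20, (H, W))  # static, rank-1 across slow time
ensemble = np.repeat(tissue[None], N, axis=0)
ensemble += 0.05 * rng.standard_normal(ensemble.shape)  # sensor noise
vessel = np.zeros((H, W), dtype=bool)
vessel[4:20, 6:24] = True  # 288 voxels >> 60 discarded components
ensemble[:, vessel] += 2.0 * rng.standard_normal((N, vessel.sum()))  # blood

power = svd_clutter_filter(ensemble, discard_fraction=0.3)

inside = power[vessel].mean()
outside = power[~vessel].mean()
print(f"discarded floor(0.3 x {N}) = 60 clutter components")
print(f"mean filtered power inside the vessel region: {inside:.3f}")
print(f"mean filtered power in tissue background:     {outside:.5f}")
print(f"contrast: {inside / outside:.0f}x — blood fluctuation survives while "
      "static tissue (raw power ~100x larger) is removed")
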