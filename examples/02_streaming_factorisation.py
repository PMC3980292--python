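"""Stream a movie through the online factorisation (normalise -> incremental
PCA -> convex cone) and check which true units the selected pixels recover.

The processor sees one frame at a time, exactly as frames would arrive from
a camera; at the end we ask for the current factor model and compare its
selected pixels against the ground-truth footprints.
"""

import numpy as np

import calcistream as cs
from calcistream.batch import units_hit

protocol = cs.generate_protocol(
    [f"odour_{i:02d}" for i in range(12)], interstimulus_frames=40,
    lead_in_frames=20, frame_rate=5.0, seed=1, total_frames=800,
)
truth = cs.generate_ground_truth(
    image_shape=(60, 80), n_units=8, radius_range=(3.0, 5.0),
    protocol=protocol, noise_sigma=0.2, n_background=4, seed=1,
)
movie = cs.render_movie(truth, dtype=np.float32)

config = cs.StreamConfig(k=16, c=16, spatial_filter_width=1,
                         select_every=100, compute_recon=True)
proc = cs.StreamProcessor(truth.image_shape, config)
for frame in movie:
    res = proc.process_frame(frame)
    if res.recon is not None and res.index % 200 == 0:
        rel = res.recon.residual_norm / np.linalg.norm(res.normalised)
        print(f"frame {res.index:4d}: relative residual of the low-rank "
              f"approximation = {rel:.2f}")

model = proc.current_model()
hits = units_hit(model, truth)
print(f"\nselected {model.c} pixels; "
      f"{sum(hits.values())}/{len(hits)} true units have a selected pixel "
      "inside their footprint")
print("selected positions (row, col):")
print(model.positions()[:8])
print(f"T (time series of selected pixels): {model.T.shape}, "
      f"S (coefficient images): {model.S.shape}")
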