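"""Object-based colocalization with the flipped-channel chance control.

Simulates several two-channel punctate fields in which 50% of candidate
puncta are planted to overlap a reference punctum, segments both channels
(Triangle threshold on the pooled z-stack histogram, then particle
analysis), measures the percentage of reference puncta overlapping the
candidate mask, repeats the measurement with the reference channel
mirrored horizontally, and tests original vs flipped across fields.
"""

import numpy as np

from synprox import (ImageSimConfig, SegmentationConfig, coloc_with_flip,
                     expected_chance_overlap, full_image_roi,
                     paired_comparison, segment_puncta, simulate_puncta_image)

seg = SegmentationConfig(min_area_px=12)
pairs = []
print(" field   n_ref   original%   flipped%")
for seed in range(8):
    cfg = ImageSimConfig(seed=seed, coloc_fraction=0.5,
                         width_px=256, height_px=256,
                         ref_density_per_um2=0.2, cand_density_per_um2=0.2)
    stack, _ = simulate_puncta_image(cfg)
    ref = segment_puncta(stack, 0, seg)
    cand = segment_puncta(stack, 1, seg)
    roi = full_image_roi(stack.shape_yx, stack.pixel_size_um)
    r = coloc_with_flip(ref, cand, roi)
    pairs.append((r["pct_original"], r["pct_flipped"]))
    print(f"  {seed:4d}  {r['n_ref']:5d}   {r['pct_original']:8.1f} "
          f"  {r['pct_flipped']:8.1f}")

test = paired_comparison(pairs)
chance = expected_chance_overlap(ref, cand, n_translations=500, seed=0)
orig, flip = np.mean([p[0] for p in pairs]), np.mean([p[1] for p in pairs])
print()
print(f"mean original {orig:.1f}%  vs  mean flipped {flip:.1f}%")
print(f"chance level (Boolean model {chance['analytic_percent']:.1f}%, "
      f"Monte-Carlo {chance['mc_percent']:.1f} +/- {chance['mc_se']:.2f}%)")
print(f"paired test: {test.test_name}, p = {test.p_value:.4g} "
      f"over {test.n_pairs} fields")
print("The flipped percentages sit at the chance level; the gap between")
print("original and flipped is the planted true colocalization.")
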