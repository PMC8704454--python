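"""Full completion pipeline on the chirped-arc demo, exact vs approximate.

A chirped sinusoidal arc pattern is occluded by arcs from the opposite
corner, lifted into the 5D cortical grid, diffused for T=10 with the
occluded channels as interior, and inverted.  Both the exact 5D operator and
the per-channel SE(2) approximation are run; their masked-region RMSE
against the ground truth (lower is better; the corrupted input's RMSE is the
baseline) and their mutual agreement are printed.
"""

import numpy as np

from gaborlift import CompletionConfig, complete_image, evaluate_completion
from gaborlift import synth

N = 64
truth = synth.chirped_arcs_image(N)
mask = synth.occluding_arcs_mask(N)
corrupted = np.where(mask, 0.0, truth)

print(f"occluded pixels: {mask.sum()} ({100 * mask.mean():.1f}% of the image)")
print(f"corrupted masked RMSE: {evaluate_completion(corrupted, truth, mask):.4f}")

results = {}
for mode in ("approximate", "exact"):
    res = complete_image(corrupted, mask, CompletionConfig(mode=mode))
    rmse = evaluate_completion(res, truth, mask)
    results[mode] = res
    print(f"{mode:12s}: masked RMSE {rmse:.4f} after {res.iterations} steps "
          f"(amplitude amplification {res.amplification:.3f})")

corr = np.corrcoef(results["exact"].image[mask],
                   results["approximate"].image[mask])[0, 1]
print(f"exact vs approximate correlation over the mask: {corr:.4f} "
      "(the two operators propagate structure almost identically)")
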