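"""Why multiple frequency channels matter: the single-frequency ablation.

The chirped-arc pattern spans a band of spatial frequencies.  Completing it
with the full multi-frequency lift is compared against runs where the
frequency axis is collapsed to one fixed value (the lift then loses the
other scales and the readout falls back to the channel-sum projection).
Single-frequency masked RMSEs come out strictly worse.
"""

import numpy as np

from gaborlift import (CompletionConfig, complete_image, evaluate_completion,
                       single_frequency_ablation)
from gaborlift import synth

N = 64
truth = synth.chirped_arcs_image(N)
mask = synth.occluding_arcs_mask(N)
corrupted = np.where(mask, 0.0, truth)

cfg = CompletionConfig(mode="exact")
multi = complete_image(corrupted, mask, cfg)
rmse_multi = evaluate_completion(multi, truth, mask)
print(f"multi-frequency (L={cfg.n_frequencies}): masked RMSE {rmse_multi:.4f}")

f_all = np.linspace(cfg.f_min, cfg.f_max, cfg.n_frequencies)
for f in (f_all[0], f_all[1], f_all[3]):
    single = single_frequency_ablation(corrupted, mask, float(f), cfg)
    rmse = evaluate_completion(single, truth, mask)
    print(f"single frequency f={f:.2f} rad/px: masked RMSE {rmse:.4f} "
          f"(+{rmse - rmse_multi:.4f} vs multi)")
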