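"""ICAM-1 activation quantified as a batch-normalized fold-change.

Each treated image's ROI mean is divided by the average ROI mean of the
control images from the same staining batch, which cancels illumination
and staining differences between batches. Here a 2.3-fold activation is
recovered from 12 control + 12 treated noisy synthetic images.
"""

import numpy as np

from bbbkit import ImageSimConfig, fold_change, simulate_image_batch

cfg = ImageSimConfig(
    shape=(64, 64),
    baseline_intensity=1000.0,
    fold_change=2.3,       # generator truth for treated images
    noise_sigma=50.0,      # 5% of baseline
    seed=8,
)
controls, treated = simulate_image_batch(cfg, n_control=12, n_treated=12)

res = fold_change(treated, controls)
print(f"control ratios mean: {res.control_ratios.mean():.3f} (1 by construction)")
print(f"treated fold-change: {res.mean_treated:.3f} "
      f"± {np.std(res.treated_ratios):.3f} (truth {cfg.fold_change})")
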