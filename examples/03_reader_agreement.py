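"""Simulated manual segmentations and geometric/quantitative agreement.

Two simulated 'readers' trace the nerve with a calibrated expected Dice of
0.70 against the true mask; the example measures the achieved Dice and the
effect of reader variability on the aT2* estimate.
"""
import numpy as np

from vtemri import (PhantomConfig, add_rician_noise, build_label_map,
                    dice_index, roi_at2, simulate_reader_masks,
                    simulate_signal)

config = PhantomConfig()
truth = build_label_map(config)
study = add_rician_noise(simulate_signal(truth, config),
                         config.noise_sigma, seed=3)

reader1, reader2 = simulate_reader_masks(truth.true_nerve_mask,
                                         target_dice=0.70, n_readers=2,
                                         seed=3)
d1 = dice_index(reader1, truth.true_nerve_mask)
d2 = dice_index(reader2, truth.true_nerve_mask)
d12 = dice_index(reader1, reader2)
print(f"Dice reader1 vs truth   : {d1:.3f}")
print(f"Dice reader2 vs truth   : {d2:.3f}")
print(f"Dice reader1 vs reader2 : {d12:.3f} "
      "(two independent tracings overlap less than either does the truth)")

for name, mask in [("truth", truth.true_nerve_mask),
                   ("reader1", reader1), ("reader2", reader2)]:
    s = roi_at2(study, mask, discard_extremes=2)
    print(f"aT2* with {name:8s} mask: {s.at2_roi_ms:6.2f} ms "
          f"(CSA {s.csa_mean_mm2:.1f} mm^2)")
# Reader masks admit some adjacent muscle (T2* 28 ms), nudging the ROI
# estimate above the truth-mask value — the reproducibility cost that the
# Dice/ICC battery quantifies.
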