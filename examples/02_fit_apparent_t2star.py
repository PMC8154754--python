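"""Echo subtraction and the two-point apparent-T2* estimators.

Shows that on a noiseless mono-exponential nerve both the ROI-mean and the
voxelwise estimator recover the configured T2* exactly, and that the
subtraction image highlights short-T2* tissue (fascia) over muscle.
"""
import numpy as np

from vtemri import (PhantomConfig, TissueSpec, build_label_map,
                    default_tissues, roi_at2, simulate_signal,
                    subtract_echoes, voxelwise_at2)

tissues = default_tissues()
tissues["nerve"] = TissueSpec("nerve", 650.0, ((1.0, 17.25),))
tissues["fascicle"] = TissueSpec("fascicle", 650.0, ((1.0, 17.25),))
config = PhantomConfig(tissues=tissues, supersample=1, noise_sigma=0.0)

truth = build_label_map(config)
study = simulate_signal(truth, config)

summary = roi_at2(study, truth.true_nerve_mask, discard_extremes=2)
print(f"configured nerve T2*      : 17.25 ms")
print(f"ROI-mean estimate         : {summary.at2_roi_ms:.10f} ms")
print(f"voxelwise-mean estimate   : {summary.at2_voxelwise_mean_ms:.10f} ms")
print(f"CSA over {summary.n_slices_used} slices       : "
      f"{summary.csa_mean_mm2:.1f} mm^2")

sub = subtract_echoes(study)
fascia = truth.fractions["fascia"] > 0.99
muscle = truth.fractions["muscle"] > 0.99
print(f"subtraction, fascia mean  : {sub[fascia].mean():.1f}  (short T2*, bright)")
print(f"subtraction, muscle mean  : {sub[muscle].mean():.1f}  (long T2*, dark)")

amap = voxelwise_at2(study)
print(f"invalid voxels flagged    : {amap.n_invalid} "
      "(background air: no decaying signal)")
# Both estimators agree with the ground truth to machine precision because
# two points determine a mono-exponential; they differ only for
# heterogeneous or noisy ROIs.
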