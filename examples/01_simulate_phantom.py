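"""Build a synthetic dual-echo thigh phantom and inspect its ground truth.

The phantom is a circular thigh cross-section (muscle, fascia, suppressed
fat) containing a sciatic nerve with fascicles, imaged at TE1/TE2 =
0.98/5.37 ms with Rician magnitude noise.
"""
from vtemri import (PhantomConfig, add_rician_noise, build_label_map,
                    simulate_signal, write_study)

config = PhantomConfig()                      # 96x96x12 voxels, 0.6x0.6x5 mm
truth = build_label_map(config)
study = simulate_signal(truth, config)        # noiseless echoes
noisy = add_rician_noise(study, config.noise_sigma, seed=0)

nerve = truth.true_nerve_mask
print(f"grid {config.grid}, voxel {config.voxel_size} mm")
print(f"nerve voxels per slice : {nerve.data[:, :, 0].sum()}")
print(f"true two-point aT2*    : {truth.effective_at2_ms:.2f} ms "
      "(analytic, noiseless nerve signal)")
print(f"nerve mean, echo 1     : {study.echo1[nerve.data].mean():.1f}")
print(f"nerve mean, echo 2     : {study.echo2[nerve.data].mean():.1f}")

paths = write_study(noisy, "scratch_phantom", prefix="demo_right")
print(f"wrote {sorted(p.name for p in paths.values())}")
# The effective aT2* (~20 ms here) reflects the nerve's two-pool mixture:
# 70% slow water at 50 ms plus 30% connective/myelin pool at 2 ms.
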