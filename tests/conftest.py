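import numpy as np
import pytest

from vtemri import (DualEchoStudy, PhantomConfig, ThighGeometry, TissueSpec,
                    VoxelMask, default_tissues)

TE1, TE2 = 0.98, 5.37


def single_pool_tissues(nerve_t2_ms: float, nerve_s0: float = 650.0):
    """Tissue set with a mono-exponential nerve (fascicles matched)."""
    tissues = default_tissues()
    tissues["nerve"] = TissueSpec("nerve", nerve_s0, ((1.0, nerve_t2_ms),))
    tissues["fascicle"] = TissueSpec("fascicle", nerve_s0, ((1.0, nerve_t2_ms),))
    return tissues


def small_geometry():
    return ThighGeometry(muscle_radius_mm=10.0, fascia_thickness_mm=0.8,
                         fat_thickness_mm=1.2, nerve_center_mm=(3.5, -3.5),
                         nerve_radius_mm=2.5)


def make_config(nerve_t2_ms=17.25, grid=(48, 48, 8), supersample=1,
                noise_sigma=0.0, **geom_kwargs):
    geom = small_geometry()
    if geom_kwargs:
        from dataclasses import replace
        geom = replace(geom, **geom_kwargs)
    return PhantomConfig(grid=grid, voxel_size=(0.6, 0.6, 5.0),
                         te1=TE1, te2=TE2,
                         tissues=single_pool_tissues(nerve_t2_ms),
                         geometry=geom, noise_sigma=noise_sigma,
                         supersample=supersample, seed=0)


def make_study(echo1, echo2, te1=TE1, te2=TE2, voxel=(0.6, 0.6, 5.0), **kw):
    return DualEchoStudy(echo1=np.asarray(echo1, float),
                         echo2=np.asarray(echo2, float),
                         te1=te1, te2=te2, voxel_size=voxel, **kw)


def uniform_study(s1, s2, shape=(4, 4, 3), **kw):
    return make_study(np.full(shape, float(s1)), np.full(shape, float(s2)), **kw)


def full_mask(shape=(4, 4, 3), **kw):
    return VoxelMask(np.ones(shape, dtype=bool), **kw)


@pytest.fixture(scope="session")
def single_pool_truth():
    """Noiseless single-pool phantom (supersample=1: every voxel pure)."""
    from vtemri import build_label_map, simulate_signal
    cfg = make_config(nerve_t2_ms=17.25)
    truth = build_label_map(cfg)
    study = simulate_signal(truth, cfg)
    return cfg, truth, study
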