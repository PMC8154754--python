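"""Two-point apparent-T2* relaxometry of dual-echo studies.

The quantitative core: echo subtraction (short-T2* visualisation), the
voxelwise and ROI-level two-point estimator

    aT2* = -dTE / ln(iTE2 / iTE1),

cross-sectional area, and the slice-selection rule that drops the extreme
slices of a slab before analysis.

The ROI-level estimator applies the formula to the ROI-mean intensity of
each echo (one intensity per ROI per echo); the mean of the valid voxelwise
estimates is reported alongside. For heterogeneous ROIs the two differ
(Jensen's inequality), for homogeneous or noiseless mono-exponential ROIs
they coincide.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import DualEchoStudy, VoxelMask

#: aT2* estimates above this value (ms) are retained but flagged unreliable:
#: with a ~4.4 ms echo spacing the two echoes barely differ for such slow decay.
UNRELIABLE_AT2_MS = 200.0


class NonDecayingROIError(ValueError):
    """The ROI-mean signal does not decay between the echoes."""


@dataclass
class AT2Map:
    """Voxelwise apparent-T2* map in ms.

    ``values`` is NaN wherever ``invalid`` is set (non-positive intensities
    or non-decaying signal, where the two-point formula is undefined or
    non-positive). ``unreliable`` flags finite estimates above
    :data:`UNRELIABLE_AT2_MS`; they are kept in summaries.
    """

    values: np.ndarray
    invalid: np.ndarray
    n_invalid: int
    n_unreliable: int

    @property
    def valid(self) -> np.ndarray:
        return ~self.invalid

    @property
    def unreliable(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.valid & (self.values > UNRELIABLE_AT2_MS)


@dataclass
class AT2Summary:
    """Per-study ROI summary: aT2* (ms) and CSA (mm^2)."""

    subject_id: str
    side: str
    at2_roi_ms: float
    at2_voxelwise_mean_ms: float
    csa_mean_mm2: float
    csa_per_slice_mm2: np.ndarray
    n_slices_used: int
    n_mask_voxels: int
    n_invalid_voxels: int
    n_unreliable_voxels: int
    retained_slices: tuple[int, ...]


def subtract_echoes(study: DualEchoStudy) -> np.ndarray:
    """Echo 1 minus Echo 2, floored at zero (magnitude convention).

    Long-T2* species barely decay between the echoes and are suppressed;
    short-T2* species lose most of their signal by TE2 and stand out.
    """
    diff = study.echo1 - study.echo2
    return np.maximum(diff, 0.0)


def voxelwise_at2(study: DualEchoStudy) -> AT2Map:
    """Apply the two-point formula voxel by voxel.

    Voxels where either intensity is non-positive, or where the signal does
    not decay (iTE2 >= iTE1, giving a non-positive or infinite estimate),
    are flagged invalid and set to NaN rather than raising.
    """
    e1, e2 = study.echo1, study.echo2
    invalid = (e1 <= 0) | (e2 <= 0) | (e2 >= e1)
    values = np.full(e1.shape, np.nan)
    ok = ~invalid
    with np.errstate(divide="ignore", invalid="ignore"):
        values[ok] = -study.delta_te / np.log(e2[ok] / e1[ok])
    n_unrel = int(np.sum(values[ok] > UNRELIABLE_AT2_MS))
    return AT2Map(values=values, invalid=invalid, n_invalid=int(invalid.sum()),
                  n_unreliable=n_unrel)


def retained_slice_indices(n_slices: int, k: int = 2) -> tuple[int, ...]:
    """Indices kept by the discard-extremes policy: drop k/2 from each end."""
    if k < 0 or k % 2 != 0:
        raise ValueError(f"k must be a non-negative even count, got {k}")
    if k >= n_slices:
        raise ValueError(f"cannot discard {k} of {n_slices} slices")
    h = k // 2
    return tuple(range(h, n_slices - h))


def filter_slices(obj, k: int = 2):
    """Drop the k/2 most extreme slices from each end of the slab.

    Accepts a 3D array, a :class:`VoxelMask` or a :class:`DualEchoStudy`
    and returns the same type restricted to the retained slices. The kept
    indices are available via :func:`retained_slice_indices`.
    """
    if isinstance(obj, DualEchoStudy):
        idx = retained_slice_indices(obj.n_slices, k)
        return obj.with_volumes(obj.echo1[:, :, idx], obj.echo2[:, :, idx])
    if isinstance(obj, VoxelMask):
        idx = retained_slice_indices(obj.shape[2], k)
        return replace(obj, data=obj.data[:, :, idx])
    arr = np.asarray(obj)
    if arr.ndim != 3:
        raise ValueError("expected a 3D volume")
    idx = retained_slice_indices(arr.shape[2], k)
    return arr[:, :, idx]


@dataclass
class CSAResult:
    per_slice_mm2: np.ndarray
    mean_mm2: float
    n_slices_used: int


def roi_csa(mask: VoxelMask, voxel_size: tuple[float, float, float],
            discard_extremes: int = 0) -> CSAResult:
    """Cross-sectional area per slice (voxel count x in-plane voxel area).

    The mean is taken over retained slices where the ROI is non-empty;
    empty slices report 0 mm^2.
    """
    m = filter_slices(mask, discard_extremes) if discard_extremes else mask
    dx, dy = voxel_size[0], voxel_size[1]
    counts = m.data.sum(axis=(0, 1))
    per_slice = counts * dx * dy
    nonempty = counts > 0
    mean = float(per_slice[nonempty].mean()) if nonempty.any() else 0.0
    return CSAResult(per_slice_mm2=per_slice.astype(float), mean_mm2=mean,
                     n_slices_used=int(nonempty.sum()))


def roi_at2(study: DualEchoStudy, mask: VoxelMask,
            discard_extremes: int = 0) -> AT2Summary:
    """ROI-level apparent-T2* from ROI-mean intensities.

    The primary estimate applies the two-point formula to the mean echo-1
    and echo-2 intensities over the (slice-filtered) mask. The mean of the
    valid voxelwise estimates inside the mask is reported for comparison.
    """
    if not mask.matches(study):
        raise ValueError(
            f"mask shape {mask.shape} does not match study shape {study.shape}")
    if discard_extremes:
        study_f = filter_slices(study, discard_extremes)
        mask_f = filter_slices(mask, discard_extremes)
        retained = retained_slice_indices(study.n_slices, discard_extremes)
    else:
        study_f, mask_f = study, mask
        retained = tuple(range(study.n_slices))
    if mask_f.is_empty:
        raise ValueError("empty ROI after slice filtering")

    sel = mask_f.data
    m1 = float(study_f.echo1[sel].mean())
    m2 = float(study_f.echo2[sel].mean())
    if m2 >= m1:
        raise NonDecayingROIError(
            f"non-decaying ROI: mean(echo2)={m2:.4g} >= mean(echo1)={m1:.4g}")
    at2_roi = -study_f.delta_te / np.log(m2 / m1)

    amap = voxelwise_at2(study_f)
    vox_valid = amap.valid & sel
    n_invalid = int((amap.invalid & sel).sum())
    n_unrel = int((amap.unreliable & sel).sum())
    at2_vox = float(amap.values[vox_valid].mean()) if vox_valid.any() else float("nan")

    csa = roi_csa(mask_f, study.voxel_size)
    return AT2Summary(
        subject_id=study.subject_id,
        side=study.side,
        at2_roi_ms=float(at2_roi),
        at2_voxelwise_mean_ms=at2_vox,
        csa_mean_mm2=csa.mean_mm2,
        csa_per_slice_mm2=csa.per_slice_mm2,
        n_slices_used=csa.n_slices_used,
        n_mask_voxels=int(sel.sum()),
        n_invalid_voxels=n_invalid,
        n_unreliable_voxels=n_unrel,
        retained_slices=retained,
    )
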