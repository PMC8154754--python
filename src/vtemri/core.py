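"""Core containers shared across the pipeline.

A :class:`DualEchoStudy` holds the two magnitude volumes of a dual-echo
acquisition together with their echo times and voxel geometry; a
:class:`VoxelMask` is a binary region of interest aligned to such a study.
Volumes are indexed ``[x, y, z]`` (column, row, slice), matching the NIfTI
axis order used throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

SIDES = ("right", "left")


@dataclass
class DualEchoStudy:
    """Paired magnitude volumes from one dual-echo acquisition.

    Parameters
    ----------
    echo1, echo2 : ndarray, shape (nx, ny, nslices)
        Magnitude images at the first and second echo. Non-negative.
    te1, te2 : float
        Echo times in milliseconds, ``0 < te1 < te2``.
    voxel_size : tuple of float
        ``(dx, dy, dz)`` voxel edge lengths in millimetres.
    """

    echo1: np.ndarray
    echo2: np.ndarray
    te1: float
    te2: float
    voxel_size: tuple[float, float, float] = (0.6, 0.6, 5.0)
    subject_id: str = ""
    side: str = "right"

    def __post_init__(self) -> None:
        self.echo1 = np.asarray(self.echo1, dtype=float)
        self.echo2 = np.asarray(self.echo2, dtype=float)
        if self.echo1.ndim != 3:
            raise ValueError(f"echo volumes must be 3D, got ndim={self.echo1.ndim}")
        if self.echo1.shape != self.echo2.shape:
            raise ValueError(
                f"echo dimension mismatch: {self.echo1.shape} vs {self.echo2.shape}"
            )
        if not (0 < self.te1 < self.te2):
            raise ValueError(f"need 0 < te1 < te2, got te1={self.te1}, te2={self.te2}")
        if np.nanmin(self.echo1) < 0 or np.nanmin(self.echo2) < 0:
            raise ValueError("magnitude volumes must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"invalid voxel_size {self.voxel_size}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.echo1.shape

    @property
    def n_slices(self) -> int:
        return self.echo1.shape[2]

    @property
    def delta_te(self) -> float:
        """Echo-time difference TE2 - TE1 in ms."""
        return self.te2 - self.te1

    def with_volumes(self, echo1: np.ndarray, echo2: np.ndarray) -> "DualEchoStudy":
        return replace(self, echo1=echo1, echo2=echo2)


@dataclass
class VoxelMask:
    """Binary 3D region of interest aligned to a study grid."""

    data: np.ndarray
    label: str = "nerve"
    reader: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={arr.ndim}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("mask values must be in {0, 1}")
        self.data = arr.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not self.data.any()

    def matches(self, study: DualEchoStudy) -> bool:
        return self.shape == study.shape

    def with_provenance(self, reader: str | None = None, timepoint: str | None = None) -> "VoxelMask":
        return replace(
            self,
            reader=self.reader if reader is None else reader,
            timepoint=self.timepoint if timepoint is None else timepoint,
        )
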