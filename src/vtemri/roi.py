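"""Polygonal ROIs, rasterization, cross-echo mask transfer and Dice overlap.

Polygons live in image-plane millimetre coordinates; voxel (i, j) on a slice
has its centre at (i*dx, j*dy) (centre-of-voxel convention, x = column,
y = row). A voxel belongs to the rasterized ROI iff its centre is inside the
polygon; centres lying exactly on an edge count as inside.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import numpy as np
from matplotlib.path import Path as MplPath

from .core import DualEchoStudy, VoxelMask

_EDGE_EPS = 1e-9

ROI_LABELS = ("nerve", "muscle", "background_noise")


@dataclass
class PolygonROI:
    """Per-slice closed polygon chains delineating one structure.

    ``slices`` maps slice index -> list of chains, each chain an (n, 2)
    array of (x_mm, y_mm) vertices. Chains need >= 3 vertices and are
    treated as closed.
    """

    slices: dict[int, list[np.ndarray]]
    label: str = "nerve"

    def __post_init__(self) -> None:
        clean: dict[int, list[np.ndarray]] = {}
        for idx, chains in self.slices.items():
            out = []
            for chain in chains:
                arr = np.asarray(chain, dtype=float)
                if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                    raise ValueError(
                        f"slice {idx}: each chain needs >=3 (x, y) vertices, "
                        f"got shape {arr.shape}")
                out.append(arr)
            clean[int(idx)] = out
        self.slices = clean

    # -- JSON schema: {"label": ..., "slices": [{"index": i, "chains": [[[x, y], ...]]}]}
    def to_json(self, path: str | FsPath) -> None:
        payload = {
            "label": self.label,
            "slices": [
                {"index": idx, "chains": [c.tolist() for c in chains]}
                for idx, chains in sorted(self.slices.items())
            ],
        }
        FsPath(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | FsPath) -> "PolygonROI":
        payload = json.loads(FsPath(path).read_text())
        slices = {
            int(entry["index"]): [np.asarray(c, dtype=float) for c in entry["chains"]]
            for entry in payload["slices"]
        }
        return cls(slices=slices, label=payload.get("label", "nerve"))

    def shoelace_area_mm2(self, slice_index: int) -> float:
        """Analytic (shoelace) area of the chains on one slice, mm^2."""
        total = 0.0
        for chain in self.slices[slice_index]:
            x, y = chain[:, 0], chain[:, 1]
            total += 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        return total


def _points_in_chain(points: np.ndarray, chain: np.ndarray) -> np.ndarray:
    path = MplPath(chain)  # contains_points treats the chain as closed
    # boundary tie-break: a centre on the edge counts as inside, regardless
    # of vertex orientation (radius sign flips with winding direction)
    return path.contains_points(points, radius=_EDGE_EPS) | \
        path.contains_points(points, radius=-_EDGE_EPS)


def rasterize_polygon(roi: PolygonROI, grid: tuple[int, int, int],
                      voxel_size: tuple[float, float, float]) -> VoxelMask:
    """Rasterize a polygon ROI onto a voxel grid (voxel-centre inclusion test)."""
    nx, ny, nz = grid
    dx, dy = voxel_size[0], voxel_size[1]
    xs = np.arange(nx) * dx
    ys = np.arange(ny) * dy
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel()])
    data = np.zeros(grid, dtype=bool)
    for idx, chains in roi.slices.items():
        if not 0 <= idx < nz:
            raise ValueError(f"slice index {idx} outside grid with {nz} slices")
        inside = np.zeros(nx * ny, dtype=bool)
        for chain in chains:
            inside |= _points_in_chain(points, chain)
        data[:, :, idx] = inside.reshape(nx, ny)
    return VoxelMask(data=data, label=roi.label)


def transfer_mask(mask: VoxelMask, target: DualEchoStudy) -> VoxelMask:
    """Transfer a mask between co-registered echo sets (identity on the grid).

    Both echoes of a dual-echo acquisition share one grid, so the transfer
    only asserts dimensional equality and updates provenance; no resampling
    is offered.
    """
    if not mask.matches(target):
        raise ValueError(
            f"grid mismatch: mask {mask.shape} vs study {target.shape}; "
            "no resampling is supported")
    return VoxelMask(data=mask.data.copy(), label=mask.label,
                     reader=mask.reader, timepoint=mask.timepoint)


def dice_index(a: VoxelMask, b: VoxelMask) -> float:
    """Dice overlap 2|A. B| / (|A| + |B|) of two same-grid masks."""
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise ValueError("Dice undefined: both masks are empty")
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)
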