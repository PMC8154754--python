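"""NIfTI + JSON-sidecar IO for dual-echo studies and masks.

One NIfTI volume per echo with the voxel size encoded in the affine, and a
BIDS-like JSON sidecar carrying ``EchoTime1``/``EchoTime2`` in seconds
(converted to milliseconds internally).
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import DualEchoStudy, VoxelMask


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_study(study: DualEchoStudy, out_dir: str | Path,
                prefix: str | None = None) -> dict[str, Path]:
    """Write echo1/echo2 NIfTI volumes and the JSON sidecar; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if prefix is None:
        prefix = f"{study.subject_id or 'study'}_{study.side}"
    aff = _affine(study.voxel_size)
    paths = {}
    for name, vol in (("echo1", study.echo1), ("echo2", study.echo2)):
        p = out_dir / f"{prefix}_{name}.nii.gz"
        # float64 on disk: round-trips are exact, not merely close
        nib.save(nib.Nifti1Image(vol.astype(np.float64), aff), p)
        paths[name] = p
    sidecar = {
        "EchoTime1": study.te1 / 1000.0,
        "EchoTime2": study.te2 / 1000.0,
        "VoxelSizeMm": list(study.voxel_size),
        "SubjectId": study.subject_id,
        "Side": study.side,
    }
    p = out_dir / f"{prefix}.json"
    p.write_text(json.dumps(sidecar, indent=2))
    paths["sidecar"] = p
    return paths


def _raw_zooms(path: str | Path) -> np.ndarray:
    """In-plane/slice pixdim as stored on disk, without nibabel's auto-repair
    (a zero pixdim would otherwise be silently reset to 1)."""
    from nibabel.openers import ImageOpener
    with ImageOpener(str(path), "rb") as f:
        hdr = nib.Nifti1Header.from_fileobj(f, check=False)
    return np.asarray(hdr["pixdim"][1:4], dtype=float)


def read_study(echo1_path: str | Path, echo2_path: str | Path,
               sidecar_path: str | Path) -> DualEchoStudy:
    """Load a dual-echo study; validates pixdim and echo-time ordering."""
    if np.any(_raw_zooms(echo1_path) <= 0):
        raise ValueError(f"{echo1_path}: NIfTI header has no valid pixdim")
    imgs = [nib.load(str(p)) for p in (echo1_path, echo2_path)]
    vols = [np.asarray(img.dataobj, dtype=float) for img in imgs]
    zooms = imgs[0].header.get_zooms()[:3]
    meta = json.loads(Path(sidecar_path).read_text())
    for key in ("EchoTime1", "EchoTime2"):
        if key not in meta:
            raise ValueError(f"{sidecar_path}: sidecar missing {key}")
    te1 = float(meta["EchoTime1"]) * 1000.0
    te2 = float(meta["EchoTime2"]) * 1000.0
    if te2 <= te1:
        raise ValueError(
            f"{sidecar_path}: EchoTime2 ({te2} ms) must exceed EchoTime1 ({te1} ms)")
    return DualEchoStudy(
        echo1=vols[0], echo2=vols[1], te1=te1, te2=te2,
        voxel_size=tuple(float(z) for z in zooms),
        subject_id=str(meta.get("SubjectId", "")),
        side=str(meta.get("Side", "right")))


def write_mask(mask: VoxelMask, path: str | Path,
               voxel_size=(0.6, 0.6, 5.0)) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), _affine(voxel_size)), path)
    return path


def read_mask(path: str | Path, label: str = "nerve") -> VoxelMask:
    img = nib.load(str(path))
    return VoxelMask(data=np.asarray(img.dataobj) > 0, label=label)
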