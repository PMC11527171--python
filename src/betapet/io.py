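"""NIfTI-1 and tabular readers/writers.

Volumes are stored as uncompressed NIfTI-1 float32 in RAS+ orientation
with a diagonal affine built from the voxel spacing.  Region mask sets are
stored as an integer label volume plus a JSON sidecar carrying the
code-to-label legend, bilateral flags and the midline coordinate.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .roi import RegionMaskSet, ScanVolume

NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag([*voxel_size_mm, 1.0]).astype(float)
    return aff


def _check_path(path: Path) -> Path:
    path = Path(path)
    if not str(path).endswith(NIFTI_SUFFIXES):
        raise ValueError(f"expected a NIfTI file (.nii/.nii.gz), got {path.name!r}")
    return path


def write_volume(vol: ScanVolume, path) -> None:
    path = _check_path(path)
    img = nib.Nifti1Image(vol.voxels.astype(np.float32), _affine(vol.voxel_size_mm))
    img.header.set_xyzt_units("mm")
    img.header["descrip"] = f"{vol.subject_id}|{vol.session}|norm={int(vol.normalized)}".encode()
    nib.save(img, str(path))


def read_volume(path, subject_id: str | None = None, session: str | None = None) -> ScanVolume:
    """Load a NIfTI volume; subject/session default to the header descrip
    field written by :func:`write_volume`."""
    path = _check_path(path)
    img = nib.load(str(path))
    try:
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as exc:  # pragma: no cover - malformed header
        raise ValueError(f"malformed NIfTI header in {path}: voxel sizes unreadable") from exc
    descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="replace")
    parts = descrip.split("|")
    normalized = False
    if len(parts) == 3 and parts[2].startswith("norm="):
        subject_id = subject_id or parts[0]
        session = session or parts[1]
        normalized = parts[2] == "norm=1"
    return ScanVolume(
        subject_id=subject_id or path.stem,
        session=session or "F1",
        voxels=np.asarray(img.dataobj, dtype=np.float64),
        voxel_size_mm=zooms,
        normalized=normalized,
    )


def write_mask_set(masks: RegionMaskSet, path) -> None:
    """Store a mask set as a label volume plus a JSON legend sidecar."""
    path = _check_path(path)
    label = np.zeros(masks.grid_shape, dtype=np.int16)
    legend = {}
    for i, (code, mask) in enumerate(sorted(masks.regions.items()), start=1):
        label[mask] = i
        legend[code] = i
    img = nib.Nifti1Image(label, _affine((1.0, 1.0, 1.0)))
    nib.save(img, str(path))
    sidecar = {
        "legend": legend,
        "bilateral": {c: bool(b) for c, b in masks.bilateral.items()},
        "midline_x": int(masks.midline_x),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_mask_set(path) -> RegionMaskSet:
    path = _check_path(path)
    img = nib.load(str(path))
    label = np.asarray(img.dataobj).astype(int)
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    regions = {code: label == lab for code, lab in sidecar["legend"].items()}
    return RegionMaskSet(
        regions=regions,
        midline_x=sidecar["midline_x"],
        bilateral=sidecar["bilateral"],
    )


def write_brain_mask(mask: np.ndarray, voxel_size_mm, path) -> None:
    path = _check_path(path)
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(voxel_size_mm))
    nib.save(img, str(path))


def read_brain_mask(path) -> np.ndarray:
    path = _check_path(path)
    return np.asarray(nib.load(str(path)).dataobj).astype(bool)
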