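"""NIfTI persistence for labeled image volumes (via nibabel)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from ..fields import LabeledImageVolume

__all__ = ["save_labeled_image", "load_labeled_image"]

_SIDE_CAR = "rois.json"


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_labeled_image(directory, image: LabeledImageVolume) -> Path:
    """Write image.nii.gz plus one mask NIfTI per ROI and a name sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(image.spacing)
    nib.save(nib.Nifti1Image(image.voxels, aff), directory / "image.nii.gz")
    roi_files = {}
    for name, mask in image.masks.items():
        fname = f"mask_{name}.nii.gz"
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff), directory / fname)
        roi_files[name] = fname
    sidecar = directory / _SIDE_CAR
    with open(sidecar, "w") as fh:
        json.dump({"image": "image.nii.gz", "masks": roi_files}, fh, indent=2)
    return sidecar


def load_labeled_image(directory) -> LabeledImageVolume:
    directory = Path(directory)
    with open(directory / _SIDE_CAR) as fh:
        sidecar = json.load(fh)
    img = nib.load(directory / sidecar["image"])
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    masks = {}
    for name, fname in sidecar["masks"].items():
        masks[name] = np.asarray(nib.load(directory / fname).dataobj) > 0
    return LabeledImageVolume(np.asarray(img.dataobj, dtype=float), spacing, masks)
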