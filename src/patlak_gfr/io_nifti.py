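"""NIfTI I/O for dynamic series and integer-labelled ROI masks (via nibabel)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .preprocessing import DynamicSeries, RoiSet

__all__ = [
    "load_series_nifti",
    "save_series_nifti",
    "load_masks_nifti",
    "save_masks_nifti",
    "MASK_LABELS",
]

#: Integer label assigned to each ROI in a labelled mask volume.
MASK_LABELS = {
    "aorta_all": 1,
    "kidney_right": 2,
    "kidney_left": 3,
    "correction_aorta": 4,
    "correction_right": 5,
    "correction_left": 6,
    "cortex_right": 7,
    "cortex_left": 8,
    "a_renalis_dexter": 9,
    "highest_si": 10,
}


def load_series_nifti(path: str | Path, frame_interval: float = 0.58) -> DynamicSeries:
    """Load a 4D (x, y, z, t) or 3D (x, y, t) NIfTI as a time-first series."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        frames = np.moveaxis(data, -1, 0)  # (t, x, y, z)
    elif data.ndim == 3:
        frames = np.moveaxis(data, -1, 0)  # (t, x, y)
    else:
        raise ValueError(f"expected 3D or 4D NIfTI, got {data.ndim}D")
    zooms = img.header.get_zooms()
    dt = float(zooms[-1]) if len(zooms) == data.ndim and zooms[-1] > 0 else frame_interval
    return DynamicSeries(frames=frames, frame_interval=dt)


def save_series_nifti(series: DynamicSeries, path: str | Path) -> Path:
    """Write a series time-last with the frame interval in the last zoom."""
    data = np.moveaxis(series.frames, 0, -1)
    img = nib.Nifti1Image(data.astype(np.float32), affine=np.eye(4))
    zooms = [1.0] * (data.ndim - 1) + [series.frame_interval]
    img.header.set_zooms(zooms)
    nib.save(img, str(path))
    return Path(path)


def load_masks_nifti(path: str | Path, labels: dict[str, int] | None = None) -> RoiSet:
    """Load ROI masks from an integer-labelled volume or a one-hot stack.

    A trailing axis of length ``len(labels)`` marks the one-hot layout used
    for overlapping ROIs (e.g. small aortic sub-ROIs inside the lumen);
    anything else is read as a single labelled volume.
    """
    labels = labels or MASK_LABELS
    data = np.asarray(nib.load(str(path)).dataobj)
    masks = {}
    if data.ndim >= 3 and data.shape[-1] == len(labels):
        for name, value in labels.items():
            mask = data[..., value - 1] > 0
            if mask.any():
                masks[name] = mask
    else:
        for name, value in labels.items():
            mask = data == value
            if mask.any():
                masks[name] = mask
    if not masks:
        raise ValueError("no known ROI labels present in mask volume")
    return RoiSet(masks=masks)


def save_masks_nifti(rois: RoiSet, path: str | Path, labels: dict[str, int] | None = None) -> Path:
    """Write masks as a labelled volume, or a one-hot stack if ROIs overlap."""
    labels = labels or MASK_LABELS
    shape = next(iter(rois.masks.values())).shape
    total = np.zeros(shape, dtype=np.int16)
    for mask in rois.masks.values():
        total += mask
    if np.any(total > 1):  # overlapping ROIs need one plane per label
        data = np.zeros(shape + (len(labels),), dtype=np.int16)
        for name, mask in rois.masks.items():
            if name in labels:
                data[..., labels[name] - 1] = mask
    else:
        data = np.zeros(shape, dtype=np.int16)
        for name, mask in rois.masks.items():
            data[mask] = labels.get(name, 0)
    nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))
    return Path(path)
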