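"""Slice I/O: PNG image/mask pairs and NIfTI volume/label pairs.

Images are normalized to [0,1] at load regardless of on-disk dtype; PNG
images are stored as 16-bit grayscale (round trip preserves intensities
to 16-bit quantization), masks as 8-bit {0,255} and normalized to {0,1}
on read. NIfTI volumes are stacked per case along the third axis.
"""

from __future__ import annotations

import re
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import FoldAssignment, PhantomSlice

_PNG_RE = re.compile(r"^(\d+)_(\d+)_img\.png$")

FORMATS = ("png", "nifti")


def _normalize_image(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return (arr / 255.0).astype(np.float32)
    if arr.dtype == np.uint16:
        return (arr / 65535.0).astype(np.float32)
    arr = arr.astype(np.float32)
    hi = float(arr.max()) if arr.size else 1.0
    if hi > 1.0:
        arr = arr / hi
    return arr


def _normalize_mask(arr: np.ndarray) -> np.ndarray:
    return (np.asarray(arr) > 0).astype(np.uint8)


def write_slices(slices, path, format="png"):
    """Write slices to ``path``; see module docstring for conventions."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if format == "png":
        for s in slices:
            img16 = np.round(np.clip(s.image, 0, 1) * 65535).astype(np.uint16)
            iio.imwrite(path / f"{s.case_id}_{s.slice_id}_img.png", img16)
            iio.imwrite(
                path / f"{s.case_id}_{s.slice_id}_mask.png",
                (s.mask * 255).astype(np.uint8),
            )
    elif format == "nifti":
        by_case: dict[int, list[PhantomSlice]] = {}
        for s in slices:
            by_case.setdefault(s.case_id, []).append(s)
        for case_id, case_slices in by_case.items():
            case_slices.sort(key=lambda s: s.slice_id)
            img = np.stack([s.image for s in case_slices], axis=-1).astype(np.float32)
            msk = np.stack([s.mask for s in case_slices], axis=-1).astype(np.uint8)
            nib.save(nib.Nifti1Image(img, np.eye(4)), path / f"case_{case_id}_img.nii")
            nib.save(nib.Nifti1Image(msk, np.eye(4)), path / f"case_{case_id}_mask.nii")
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def read_slices(path, format="png") -> list[PhantomSlice]:
    path = Path(path)
    out: list[PhantomSlice] = []
    if format == "png":
        for img_path in sorted(path.glob("*_img.png")):
            m = _PNG_RE.match(img_path.name)
            if not m:
                continue
            case_id, slice_id = int(m.group(1)), int(m.group(2))
            mask_path = path / f"{case_id}_{slice_id}_mask.png"
            if not mask_path.exists():
                raise FileNotFoundError(f"missing mask for {img_path.name}")
            image = _normalize_image(iio.imread(img_path))
            mask = _normalize_mask(iio.imread(mask_path))
            if image.shape != mask.shape:
                raise ValueError(f"shape mismatch for case {case_id} slice {slice_id}")
            out.append(PhantomSlice(image, mask, case_id, slice_id))
    elif format == "nifti":
        for img_path in sorted(path.glob("case_*_img.nii*")):
            case_id = int(img_path.name.split("_")[1])
            mask_path = _sibling_nifti(path, case_id)
            img = np.asarray(nib.load(img_path).dataobj)
            msk = np.asarray(nib.load(mask_path).dataobj)
            if img.shape != msk.shape:
                raise ValueError(f"volume/label shape mismatch for case {case_id}")
            img = _normalize_image(img)
            for slice_id in range(img.shape[-1]):
                out.append(
                    PhantomSlice(
                        img[..., slice_id],
                        _normalize_mask(msk[..., slice_id]),
                        case_id,
                        slice_id,
                    )
                )
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    out.sort(key=lambda s: (s.case_id, s.slice_id))
    return out


def _sibling_nifti(path: Path, case_id: int) -> Path:
    for suffix in (".nii", ".nii.gz"):
        cand = path / f"case_{case_id}_mask{suffix}"
        if cand.exists():
            return cand
    raise FileNotFoundError(f"missing label volume for case {case_id}")


def write_manifest(slices, folds: FoldAssignment, path, format="png"):
    """Dataset manifest CSV: case_id, slice_id, fold, file paths."""
    rows = []
    for s in slices:
        if format == "png":
            img, msk = f"{s.case_id}_{s.slice_id}_img.png", f"{s.case_id}_{s.slice_id}_mask.png"
        else:
            img, msk = f"case_{s.case_id}_img.nii", f"case_{s.case_id}_mask.nii"
        rows.append(
            {
                "case_id": s.case_id,
                "slice_id": s.slice_id,
                "fold": folds.fold_of(s.case_id),
                "image_path": img,
                "mask_path": msk,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
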