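"""Volume and table readers/writers.

Conventions
-----------
* Image volumes are NIfTI, shape (rows, cols, slices), HU values; the header
  zooms carry (row spacing, col spacing, slice thickness) in mm.
* Mask volumes are integer NIfTI of the same shape: 0 = background,
  1 = lumen sampling zone, 2 = vessel wall / remainder of the aorta.
* The level table is a CSV with columns ``slice_index`` (0-based) and
  ``level`` (L1-L4); slices absent from the table are flagged unlabeled.
* All delimited output uses period decimal separators regardless of locale.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .calcium import LEVELS, AortaMask, AxialSlice
from .errors import InputError
from .phantom import PhantomStudy

LUMEN_LABEL = 1
WALL_LABEL = 2


def write_study(study: PhantomStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write a phantom study as image + mask volumes and a level table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not study.slices:
        raise InputError("cannot write an empty study")

    sr, sc = study.slices[0].pixel_spacing
    dz = study.slices[0].slice_thickness
    img = np.stack([s.hu for s in study.slices], axis=-1).astype(np.float32)
    mask = np.zeros(img.shape, dtype=np.int16)
    for k, m in enumerate(study.masks):
        mask[..., k][m.lumen_zone] = LUMEN_LABEL
        mask[..., k][m.aorta & ~m.lumen_zone] = WALL_LABEL

    affine = np.diag([sr, sc, dz, 1.0])
    paths = {
        "image": out / "image.nii.gz",
        "mask": out / "mask.nii.gz",
        "levels": out / "levels.csv",
    }
    nib.save(nib.Nifti1Image(img, affine), paths["image"])
    nib.save(nib.Nifti1Image(mask, affine), paths["mask"])
    pd.DataFrame(
        {"slice_index": range(len(study.levels)), "level": study.levels}
    ).to_csv(paths["levels"], index=False)
    return paths


def read_study(
    image_path: str | Path,
    mask_path: str | Path,
    levels_path: str | Path,
) -> list[tuple[AxialSlice, AortaMask]]:
    """Load per-slice (AxialSlice, AortaMask) pairs from disk.

    Raises typed input errors on shape mismatch, unknown mask labels, or a
    level table referencing slices outside the volume.
    """
    img_nii = nib.load(str(image_path))
    mask_nii = nib.load(str(mask_path))
    img = np.asarray(img_nii.dataobj, dtype=float)
    mask = np.asarray(mask_nii.dataobj).astype(int)
    if img.shape != mask.shape:
        raise InputError(
            f"image {img.shape} and mask {mask.shape} volumes differ in shape"
        )
    if img.ndim != 3:
        raise InputError("expected 3-D volumes (rows, cols, slices)")

    unknown = set(np.unique(mask)) - {0, LUMEN_LABEL, WALL_LABEL}
    if unknown:
        raise InputError(f"mask contains unknown labels: {sorted(unknown)}")

    sr, sc, dz = img_nii.header.get_zooms()[:3]

    table = pd.read_csv(levels_path)
    for col in ("slice_index", "level"):
        if col not in table.columns:
            raise InputError(f"level table missing column {col!r}")
    level_of: dict[int, str] = {}
    for row_no, row in enumerate(table.itertuples(index=False), start=2):
        idx = int(row.slice_index)
        if not 0 <= idx < img.shape[2]:
            raise InputError(
                f"{levels_path}, line {row_no}: slice index {idx} outside volume "
                f"of {img.shape[2]} slices"
            )
        if row.level not in LEVELS:
            raise InputError(
                f"{levels_path}, line {row_no}: unknown level {row.level!r}"
            )
        level_of[idx] = row.level

    pairs = []
    for k in range(img.shape[2]):
        slc = AxialSlice(
            hu=img[..., k],
            pixel_spacing=(float(sr), float(sc)),
            slice_thickness=float(dz),
            vertebral_level=level_of.get(k),  # None = unlabeled, ignored downstream
        )
        m = AortaMask(
            lumen_zone=mask[..., k] == LUMEN_LABEL,
            aorta=mask[..., k] > 0,
        )
        pairs.append((slc, m))
    return pairs


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """CSV writer used for metrics and report tables (header always present)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"cohort table missing columns {sorted(missing)}")
    return df
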