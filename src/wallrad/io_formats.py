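"""Read/write every external artifact the pipeline touches.

Volumes and masks are NIfTI (``.nii``/``.nii.gz``); the cohort manifest is
CSV; feature tables are TSV with a ``#``-prefixed metadata header block;
evaluation reports are JSON.  Voxel spacing comes from the NIfTI header
zooms; the affine written for synthetic data is a plain scaling.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    CaseRecord,
    EmptyMaskError,
    FeatureDescriptor,
    FeatureTable,
    GridMismatchError,
    NotHollowShellError,
    VolumeImage,
    WallMask,
    WallRadError,
    ipss_to_label,
    is_hollow_shell,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_TABLE_MAGIC = "# wallrad-feature-table v1"
MANIFEST_COLUMNS = ("case_id", "image", "mask", "age", "bmi", "prostate_size", "ipss")


def read_volume(path: PathLike) -> VolumeImage:
    """Load a 3D scalar NIfTI volume; spacing is taken from the header zooms."""
    path = Path(path)
    if not path.exists():
        raise WallRadError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise WallRadError(f"expected 3D volume, got {data.ndim}D data in {path}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise WallRadError(f"non-positive pixdim in NIfTI header of {path}: {zooms}")
    return VolumeImage(data=np.asarray(data, dtype=np.float64), spacing=tuple(float(z) for z in zooms))


def write_volume(image: VolumeImage, path: PathLike) -> None:
    affine = np.diag(list(image.spacing) + [1.0])
    nib.save(nib.Nifti1Image(image.data.astype(np.float32), affine), str(path))


def read_mask(path: PathLike, image: VolumeImage) -> WallMask:
    """Load a binary wall mask and verify it against its image.

    Nonzero voxels become foreground.  The mask must share the image's
    grid, contain foreground, and enclose a cavity (hollow-shell check).
    """
    path = Path(path)
    if not path.exists():
        raise WallRadError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise WallRadError(f"expected 3D mask, got {data.ndim}D data in {path}")
    if data.shape != image.shape:
        raise GridMismatchError(
            f"mask grid {data.shape} does not match image grid {image.shape}"
        )
    binary = (np.asarray(data) != 0).astype(np.uint8)
    if not binary.any():
        raise EmptyMaskError(f"empty mask: {path}")
    mask = WallMask(data=binary, spacing=image.spacing)
    if not is_hollow_shell(mask):
        raise NotHollowShellError(f"mask is not a hollow shell: {path}")
    return mask


def write_mask(mask: WallMask, path: PathLike) -> None:
    affine = np.diag(list(mask.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))


def crop_to_mask(
    image: VolumeImage, mask: WallMask, margin_vox: int = 0
) -> tuple[VolumeImage, WallMask]:
    """Crop image and mask to the mask's bounding box plus a voxel margin.

    The tight bounding box of the foreground is expanded by ``margin_vox``
    in every direction and clipped to the grid.  Spacing is unchanged and
    no foreground voxel is ever discarded.
    """
    if margin_vox < 0:
        raise WallRadError("margin_vox must be >= 0")
    if mask.shape != image.shape:
        raise GridMismatchError(
            f"mask grid {mask.shape} does not match image grid {image.shape}"
        )
    fg = np.argwhere(mask.data)
    lo = np.maximum(fg.min(axis=0) - margin_vox, 0)
    hi = np.minimum(fg.max(axis=0) + margin_vox + 1, mask.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return (
        VolumeImage(data=image.data[sl], spacing=image.spacing),
        WallMask(data=mask.data[sl], spacing=mask.spacing),
    )


def load_manifest(path: PathLike) -> list[CaseRecord]:
    """Load a cohort manifest CSV, excluding incomplete cases.

    Rows with any missing clinical variable (age, BMI, prostate size), a
    non-positive clinical value, or an IPSS outside [0, 35] are dropped
    and logged; labels are derived by :func:`wallrad.core.ipss_to_label`.
    """
    path = Path(path)
    if not path.exists():
        raise WallRadError(f"manifest not found: {path}")
    df = pd.read_csv(path, comment="#")
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise WallRadError(f"manifest missing columns: {missing_cols}")
    records: list[CaseRecord] = []
    n_dropped = 0
    for _, row in df.iterrows():
        reason = None
        clin = {k: row[k] for k in ("age", "bmi", "prostate_size")}
        if any(pd.isna(v) for v in clin.values()) or pd.isna(row["ipss"]):
            reason = "missing clinical parameter"
        elif any(not np.isfinite(float(v)) or float(v) <= 0 for v in clin.values()):
            reason = "non-positive clinical parameter"
        elif not (0 <= int(row["ipss"]) <= 35):
            reason = f"IPSS {row['ipss']} outside [0, 35]"
        if reason is not None:
            n_dropped += 1
            logger.info("excluding case %s: %s", row["case_id"], reason)
            continue
        records.append(
            CaseRecord(
                case_id=str(row["case_id"]),
                image_ref=None if pd.isna(row["image"]) else str(row["image"]),
                mask_ref=None if pd.isna(row["mask"]) else str(row["mask"]),
                age=float(row["age"]),
                bmi=float(row["bmi"]),
                prostate_size=float(row["prostate_size"]),
                ipss=int(row["ipss"]),
            )
        )
    logger.info("manifest %s: kept %d cases, dropped %d", path, len(records), n_dropped)
    if not records:
        raise WallRadError(f"no usable cases in manifest {path}")
    return records


def write_manifest(records: list[CaseRecord], path: PathLike, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    rows = [
        {
            "case_id": r.case_id,
            "image": r.image_ref or "",
            "mask": r.mask_ref or "",
            "age": r.age,
            "bmi": r.bmi,
            "prostate_size": r.prostate_size,
            "ipss": r.ipss,
        }
        for r in records
    ]
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(fh, index=False)


def write_feature_table(table: FeatureTable, path: PathLike) -> None:
    """Write a feature table as TSV with a descriptor header block.

    Values are written with 17 significant digits, so a round trip is
    lossless well past 12 significant digits.  Tables with non-finite
    entries are refused (the type forbids them; this guards raw arrays
    sneaking in through ``object.__setattr__`` abuse).
    """
    if not np.all(np.isfinite(table.values)):
        raise WallRadError("refusing to write feature table with non-finite entries")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_TABLE_MAGIC + "\n")
        fh.write("# descriptors\t" + json.dumps([d.to_dict() for d in table.descriptors]) + "\n")
        fh.write("case_id\t" + "\t".join(table.feature_names) + "\n")
        for cid, row in zip(table.case_ids, table.values):
            fh.write(cid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_feature_table(path: PathLike) -> FeatureTable:
    path = Path(path)
    with open(path) as fh:
        magic = fh.readline().rstrip("\n")
        if magic != _TABLE_MAGIC:
            raise WallRadError(f"not a wallrad feature table: {path}")
        desc_line = fh.readline().rstrip("\n")
        if not desc_line.startswith("# descriptors\t"):
            raise WallRadError(f"missing descriptor header in {path}")
        descriptors = tuple(
            FeatureDescriptor.from_dict(d)
            for d in json.loads(desc_line.split("\t", 1)[1])
        )
        header = fh.readline().rstrip("\n").split("\t")
        names = header[1:]
        if names != [d.name for d in descriptors]:
            raise WallRadError(f"descriptor/column mismatch in {path}")
        case_ids: list[str] = []
        rows: list[np.ndarray] = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            case_ids.append(parts[0])
            rows.append(np.array(parts[1:], dtype=np.float64))
    return FeatureTable(values=np.vstack(rows), descriptors=descriptors, case_ids=tuple(case_ids))


def labels_from_records(records: list[CaseRecord]) -> np.ndarray:
    """Binary label vector (1 = positive, IPSS >= 8) in record order."""
    return np.array([1 if r.label == "positive" else 0 for r in records], dtype=int)
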