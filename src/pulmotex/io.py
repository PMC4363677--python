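"""Volume and manifest I/O.

Volumes are read and written as NIfTI (``.nii`` / ``.nii.gz``, via nibabel)
or NRRD (``.nrrd``, via SimpleITK).  Datasets are described by a TSV manifest
with columns ``voi_path`` (relative to the manifest's directory), ``label``
and ``split``.

Stored files are interpreted in their native orientation; the pipeline treats
axes as abstract (x, y, z) since VOIs are isotropic cubes and the features are
orientation-agnostic.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

from .volume import LabeledDataset, PATTERN_LABELS, Volume, check_label

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("voi_path", "label", "split")


class UnsupportedFormatError(ValueError):
    """File extension is not one of the supported volume formats."""


def _format_of(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    if name.endswith(".nrrd"):
        return "nrrd"
    raise UnsupportedFormatError(
        f"unsupported volume format for {path.name!r}: expected "
        ".nii, .nii.gz or .nrrd"
    )


def _stem(path: Path) -> str:
    name = path.name
    for suffix in (".nii.gz", ".nii", ".nrrd"):
        if name.lower().endswith(suffix):
            return name[: -len(suffix)]
    return path.stem


def read_volume(path) -> Volume:
    """Load one VOI from a NIfTI or NRRD file.

    The identifier is the file stem.  Non-finite voxels are rejected with an
    error naming the first offending index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    fmt = _format_of(path)
    if fmt == "nifti":
        img = nib.load(str(path))
        voxels = np.asarray(img.dataobj, dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    else:
        img = sitk.ReadImage(str(path))
        # SimpleITK arrays come back (z, y, x); store as (x, y, z).
        voxels = sitk.GetArrayFromImage(img).astype(np.float64).transpose(2, 1, 0)
        spacing = tuple(float(s) for s in img.GetSpacing())
    return Volume(voxels=voxels, spacing=spacing, identifier=_stem(path)).require_finite()


def write_volume(volume: Volume, path) -> Path:
    """Write a VOI to NIfTI or NRRD, chosen by the file extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = _format_of(path)
    spacing = volume.spacing or (1.0, 1.0, 1.0)
    if fmt == "nifti":
        affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
        nib.save(nib.Nifti1Image(volume.voxels, affine), str(path))
    else:
        img = sitk.GetImageFromArray(volume.voxels.transpose(2, 1, 0))
        img.SetSpacing(tuple(spacing))
        sitk.WriteImage(img, str(path))
    return path


def save_dataset(dataset: LabeledDataset, out_dir, fmt: str = "nii.gz") -> Path:
    """Write all volumes plus a TSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (vol, label) in enumerate(zip(dataset.volumes, dataset.labels)):
        name = vol.identifier or f"voi_{i:05d}"
        rel = f"{name}.{fmt}"
        write_volume(vol, out_dir / rel)
        split = dataset.split_tags[i] if dataset.split_tags is not None else ""
        rows.append({"voi_path": rel, "label": label, "split": split})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        manifest, sep="\t", index=False
    )
    return manifest


def load_dataset(manifest_path) -> LabeledDataset:
    """Load a labeled dataset from a TSV manifest.

    Row order is preserved.  Unknown labels are rejected with a message
    listing the valid vocabulary; an empty manifest yields an empty dataset
    with a logged warning.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    table = pd.read_csv(manifest_path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("voi_path", "label"):
        if col not in table.columns:
            raise ValueError(
                f"manifest {manifest_path.name!r} is missing required column "
                f"{col!r} (required: voi_path, label; optional: split)"
            )
    if len(table) == 0:
        logger.warning("manifest %s is empty", manifest_path)
        return LabeledDataset()
    base = manifest_path.parent
    volumes, labels = [], []
    for _, row in table.iterrows():
        check_label(row["label"])
        volumes.append(read_volume(base / row["voi_path"]))
        labels.append(row["label"])
    splits = list(table["split"]) if "split" in table.columns else None
    return LabeledDataset(volumes=volumes, labels=labels, split_tags=splits)


__all__ = [
    "MANIFEST_COLUMNS",
    "PATTERN_LABELS",
    "UnsupportedFormatError",
    "load_dataset",
    "read_volume",
    "save_dataset",
    "write_volume",
]
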