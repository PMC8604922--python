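"""NIfTI I/O for preprocessed volumes, masks and cohort manifests.

The loader consumes volumes that have already been co-registered and
skull-stripped upstream; it refuses volumes without a brain mask rather
than approximating one.  Files are reoriented to canonical RAS order
before slicing, and axial slices are indexed 0-based from the inferior
end, so entropy-selected slice indices are comparable across files
regardless of on-disk storage orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import InputError
from .synthetic import VolumeRecord

__all__ = [
    "CohortManifest",
    "load_volume",
    "save_volume",
    "save_cohort",
    "load_manifest",
    "load_cohort",
]

_MANIFEST_COLUMNS = ["subject_id", "label", "volume_path", "mask_path"]


@dataclass
class CohortManifest:
    """Table of (subject_id, label, volume_path, mask_path) rows."""

    cohort_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise InputError(f"manifest is missing columns {missing}")
        ids = self.table["subject_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise InputError(f"duplicate subject_ids in manifest: {dupes}")
        labels = set(self.table["label"].astype(int))
        if not labels <= {0, 1}:
            raise InputError(f"labels must be binary, found {sorted(labels)}")


def _canonical_voxels(img: nib.spatialimages.SpatialImage, path) -> np.ndarray:
    axcodes = nib.aff2axcodes(img.affine)
    if any(code is None for code in axcodes):
        raise InputError(
            f"{path}: ambiguous affine orientation {axcodes}; refusing to guess"
        )
    canonical = nib.as_closest_canonical(img)
    data = np.asarray(canonical.get_fdata())
    if data.ndim != 3:
        raise InputError(f"{path}: expected a 3D volume, got shape {data.shape}")
    # canonical RAS array axes are (x, y, z); put the axial (z) axis first
    return np.transpose(data, (2, 1, 0))


def load_volume(
    volume_path: Union[str, Path],
    mask_path: Union[str, Path],
    subject_id: str = "",
    label: int = 0,
) -> VolumeRecord:
    """Load a preprocessed volume + mask pair into a :class:`VolumeRecord`.

    Both files are reoriented to canonical RAS order; the returned
    ``voxels`` array is ``(n_slices, height, width)`` with slice 0 at the
    inferior end.  Shape mismatches, non-finite voxels, non-binary masks
    and ambiguous affines are rejected explicitly.
    """
    volume_path, mask_path = Path(volume_path), Path(mask_path)
    voxels = _canonical_voxels(nib.load(volume_path), volume_path)
    mask_data = _canonical_voxels(nib.load(mask_path), mask_path)
    if voxels.shape != mask_data.shape:
        raise InputError(
            f"volume shape {voxels.shape} != mask shape {mask_data.shape} "
            f"({volume_path.name} vs {mask_path.name})"
        )
    if not np.all(np.isfinite(voxels)):
        raise InputError(f"{volume_path}: non-finite voxels")
    unique = np.unique(mask_data)
    if not np.all(np.isin(unique, (0.0, 1.0))):
        raise InputError(f"{mask_path}: mask values must be 0/1, found {unique[:5]}")
    return VolumeRecord(
        subject_id=subject_id or volume_path.stem.replace(".nii", ""),
        label=int(label),
        voxels=voxels,
        mask=mask_data.astype(bool),
    )


def _to_nifti(voxels: np.ndarray) -> nib.Nifti1Image:
    arr_xyz = np.transpose(np.asarray(voxels, dtype=np.float64), (2, 1, 0))
    return nib.Nifti1Image(arr_xyz, affine=np.eye(4))


def save_volume(
    record: VolumeRecord, volume_path: Union[str, Path], mask_path: Union[str, Path]
) -> None:
    """Write a record's voxels and mask as NIfTI files in RAS orientation."""
    nib.save(_to_nifti(record.voxels), str(volume_path))
    nib.save(_to_nifti(record.mask.astype(np.float64)), str(mask_path))


def save_cohort(
    cohort: Sequence[VolumeRecord],
    out_dir: Union[str, Path],
    cohort_id: str = "cohort",
) -> Path:
    """Write every volume/mask pair plus a CSV manifest; returns the manifest path."""
    if len(cohort) == 0:
        raise InputError("empty cohort")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        volume_path = out_dir / f"{rec.subject_id}_T1w.nii"
        mask_path = out_dir / f"{rec.subject_id}_mask.nii"
        save_volume(rec, volume_path, mask_path)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "label": rec.label,
                "volume_path": volume_path.name,
                "mask_path": mask_path.name,
            }
        )
    manifest_path = out_dir / f"{cohort_id}_manifest.csv"
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(manifest_path, index=False)
    return manifest_path


def load_manifest(path: Union[str, Path], cohort_id: str = "") -> CohortManifest:
    """Read and validate a cohort manifest CSV (paths resolved relative to it)."""
    path = Path(path)
    table = pd.read_csv(path)
    manifest = CohortManifest(
        cohort_id=cohort_id or path.stem.replace("_manifest", ""), table=table
    )
    for col in ("volume_path", "mask_path"):
        for p in manifest.table[col]:
            resolved = path.parent / p
            if not resolved.exists():
                raise InputError(f"manifest references missing file: {resolved}")
    return manifest


def load_cohort(
    manifest: Union[CohortManifest, str, Path], base_dir: Union[str, Path, None] = None
) -> list[VolumeRecord]:
    """Load every volume referenced by a manifest."""
    if not isinstance(manifest, CohortManifest):
        base_dir = Path(manifest).parent if base_dir is None else Path(base_dir)
        manifest = load_manifest(manifest)
    base = Path(base_dir) if base_dir is not None else Path(".")
    return [
        load_volume(
            base / row.volume_path,
            base / row.mask_path,
            subject_id=row.subject_id,
            label=int(row.label),
        )
        for row in manifest.table.itertuples()
    ]
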