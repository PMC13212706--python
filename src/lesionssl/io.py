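"""Reading and writing volumes, masks, manifests and prediction maps.

Conventions
-----------
* Arrays are indexed 0-based in ``(z, y, x)`` order, matching the on-disk
  array order; every module in the package uses this single convention.
* NIfTI affines are respected for voxel spacing only (the diagonal); the
  phantoms are generated in canonical orientation and no resampling is done.
* Volumes round-trip at float32 precision; masks round-trip exactly as
  integers.
* The manifest is a CSV with one row per case; re-saving a loaded manifest
  reproduces the file byte-for-byte apart from line endings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import CHANNELS, STATUSES, AnnotatedCase, Cohort

log = logging.getLogger("lesionssl")


@dataclass
class PredictionRecord:
    """One case's probability map, validated to lie in [0, 1] on its grid."""

    case_id: str
    prob_map: np.ndarray

    def __post_init__(self):
        self.prob_map = np.asarray(self.prob_map, dtype=np.float32)
        if not np.isfinite(self.prob_map).all():
            raise ValueError(f"probability map for {self.case_id} contains NaN/Inf")
        if self.prob_map.min() < -1e-6 or self.prob_map.max() > 1 + 1e-6:
            raise ValueError(f"probability map for {self.case_id} outside [0, 1]")


MANIFEST_COLUMNS = (
    "case_id", "t2w", "adc", "dwi", "mask",
    "status", "case_positive", "n_lesions", "lesion_volumes_mm3",
)


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(path, array: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    dtype = np.int16 if np.issubdtype(array.dtype, np.integer) else np.float32
    img = nib.Nifti1Image(np.asarray(array, dtype=dtype), _affine(spacing))
    nib.save(img, str(path))
    return path


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write every case (one NIfTI per channel, one mask) plus the manifest CSV.

    Withheld positives get an empty mask path: their annotation exists only
    inside the generator and is deliberately not released.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth = {r["case_id"]: r for _, r in cohort.manifest.iterrows()}
    for case in cohort.cases:
        paths = {}
        for i, ch in enumerate(CHANNELS):
            p = out_dir / f"{case.case_id}_{ch}.nii.gz"
            write_volume(p, case.channels[i], case.voxel_spacing)
            paths[ch] = p.name
        mask_name = ""
        if case.gt_mask is not None:
            p = out_dir / f"{case.case_id}_mask.nii.gz"
            write_volume(p, case.gt_mask.astype(np.int16), case.voxel_spacing)
            mask_name = p.name
        t = truth[case.case_id]
        rows.append({
            "case_id": case.case_id, **paths, "mask": mask_name,
            "status": case.annotation_status,
            "case_positive": str(int(case.case_positive)),
            "n_lesions": str(t["n_lesions"]),
            "lesion_volumes_mm3": t["lesion_volumes_mm3"],
        })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest_path = out_dir / "manifest.csv"
    save_manifest(manifest, manifest_path)
    log.info("wrote cohort of %d cases to %s", len(cohort.cases), out_dir)
    return manifest_path


def save_manifest(manifest: pd.DataFrame, path) -> Path:
    path = Path(path)
    manifest.astype(str).to_csv(path, index=False, lineterminator="\n")
    return path


def load_manifest(path, check_files: bool = True) -> pd.DataFrame:
    """Load and validate a cohort manifest.

    Checks: unique case ids, closed status vocabulary, referenced files
    present (unless ``check_files=False``).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise ValueError(f"duplicate case ids in manifest: {dupes}")
    bad = set(df["status"]) - set(STATUSES)
    if bad:
        raise ValueError(f"unknown annotation statuses in manifest: {sorted(bad)}")
    if check_files:
        root = path.parent
        for _, row in df.iterrows():
            for col in (*CHANNELS, "mask"):
                if row[col] and not (root / row[col]).exists():
                    raise FileNotFoundError(
                        f"manifest references missing file {root / row[col]}")
    return df


def read_case(row, root) -> AnnotatedCase:
    """Load one manifest row into an :class:`AnnotatedCase`.

    All three channels must be co-registered (identical shape and affine);
    a mismatch is a hard error naming the offending file.
    """
    root = Path(root)
    arrays, affines = [], []
    for ch in CHANNELS:
        arr, aff = read_volume(root / row[ch])
        arrays.append(np.asarray(arr, dtype=np.float32))
        affines.append(aff)
    ref_shape, ref_aff = arrays[0].shape, affines[0]
    for ch, arr, aff in zip(CHANNELS, arrays, affines):
        if arr.shape != ref_shape or not np.allclose(aff, ref_aff, atol=1e-6):
            raise ValueError(
                f"channel file {root / row[ch]} is not co-registered with "
                f"{root / row[CHANNELS[0]]}: shape {arr.shape} vs {ref_shape}"
            )
    mask = None
    if row["mask"]:
        m, m_aff = read_volume(root / row["mask"])
        if m.shape != ref_shape or not np.allclose(m_aff, ref_aff, atol=1e-6):
            raise ValueError(
                f"mask file {root / row['mask']} is not co-registered with "
                f"{root / row[CHANNELS[0]]}: shape {m.shape} vs {ref_shape}"
            )
        mask = np.asarray(m, dtype=np.int16)
    spacing = tuple(float(ref_aff[i, i]) for i in range(3))
    return AnnotatedCase(
        case_id=row["case_id"],
        channels=np.stack(arrays),
        gt_mask=mask,
        case_positive=bool(int(row["case_positive"])),
        annotation_status=row["status"],
        voxel_spacing=spacing,
    )


def read_cohort(manifest_path) -> list:
    path = Path(manifest_path)
    df = load_manifest(path)
    return [read_case(row, path.parent) for _, row in df.iterrows()]


def write_prediction(case_id: str, prob_map: np.ndarray, out_dir,
                     spacing=(1.0, 1.0, 1.0)) -> Path:
    """Write a probability map as NIfTI; refuses non-finite or out-of-range maps."""
    prob_map = np.asarray(prob_map)
    if not np.isfinite(prob_map).all():
        raise ValueError(f"probability map for {case_id} contains NaN/Inf")
    if prob_map.min() < -1e-6 or prob_map.max() > 1 + 1e-6:
        raise ValueError(f"probability map for {case_id} outside [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return write_volume(out_dir / f"{case_id}_pred.nii.gz",
                        prob_map.astype(np.float32), spacing)


def read_prediction(case_id: str, pred_dir) -> np.ndarray:
    arr, _ = read_volume(Path(pred_dir) / f"{case_id}_pred.nii.gz")
    return np.asarray(arr, dtype=np.float32)
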