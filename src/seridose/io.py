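"""File exchange: DVH CSV, NIfTI volumes/vector fields, PCSI and manifest CSV.

DVH CSV layout: two comment header lines carrying the organ label and volume,
then ``dose_gy,volume_fraction`` rows of the cumulative curve::

    # organ=bladder
    # organ_volume_cc=123.456
    dose_gy,volume_fraction
    0.0,1.0
    ...

Volumes are NIfTI (.nii / .nii.gz) with axis-aligned affines: spacing on the
diagonal, origin in the translation column.  Deformation fields are 4-D NIfTI
with the three displacement components (mm) on the last axis.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .accumulation import FractionRecord
from .grids import DeformationField, DoseGrid
from .dvh import CumulativeDVH
from .outcomes import PCSIRecord

__all__ = [
    "write_dvh_csv",
    "read_dvh_csv",
    "write_dose_nifti",
    "read_dose_nifti",
    "write_dvf_nifti",
    "read_dvf_nifti",
    "write_pcsi_csv",
    "read_pcsi_csv",
    "read_fraction_manifest",
]


def write_dvh_csv(cdvh: CumulativeDVH, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# organ={cdvh.label}\n")
        fh.write(f"# organ_volume_cc={cdvh.organ_volume_cc:.6f}\n")
        fh.write("dose_gy,volume_fraction\n")
        for d, v in zip(cdvh.bin_edges, cdvh.volume_fraction):
            fh.write(f"{d:.6f},{v:.9f}\n")


def read_dvh_csv(path) -> CumulativeDVH:
    path = Path(path)
    label = ""
    volume = None
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").strip().partition("=")
            if key == "organ":
                label = val
            elif key == "organ_volume_cc":
                volume = float(val)
    if volume is None:
        raise ValueError(f"{path}: missing organ_volume_cc header")
    df = pd.read_csv(path, comment="#")
    return CumulativeDVH(
        bin_edges=df["dose_gy"].to_numpy(),
        volume_fraction=df["volume_fraction"].to_numpy(),
        organ_volume_cc=volume,
        label=label,
    )


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _spacing_origin(img) -> tuple[tuple, tuple]:
    aff = img.affine
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diagonal(rot)), atol=1e-6):
        raise ValueError("only axis-aligned NIfTI volumes are supported")
    spacing = tuple(np.abs(np.diagonal(rot)))
    origin = tuple(aff[:3, 3])
    return spacing, origin


def write_dose_nifti(dose: DoseGrid, path) -> None:
    img = nib.Nifti1Image(dose.values.astype(np.float32), _affine(dose.spacing, dose.origin))
    nib.save(img, str(path))


def read_dose_nifti(path) -> DoseGrid:
    img = nib.load(str(path))
    spacing, origin = _spacing_origin(img)
    return DoseGrid(np.asarray(img.dataobj, dtype=float), spacing, origin)


def write_dvf_nifti(dvf: DeformationField, path) -> None:
    img = nib.Nifti1Image(
        dvf.displacements.astype(np.float32), _affine(dvf.spacing, dvf.origin)
    )
    nib.save(img, str(path))


def read_dvf_nifti(path) -> DeformationField:
    img = nib.load(str(path))
    spacing, origin = _spacing_origin(img)
    return DeformationField(np.asarray(img.dataobj, dtype=float), spacing, origin)


def write_pcsi_csv(records: list[PCSIRecord], path) -> None:
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "symptom_id": [r.symptom_id for r in records],
            "timepoint": [r.timepoint for r in records],
            "level": [r.level for r in records],
            "scale_max": [r.scale_max for r in records],
        }
    ).to_csv(path, index=False)


def read_pcsi_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "symptom_id", "timepoint", "level"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"PCSI CSV missing columns: {sorted(missing)}")
    return df


def read_fraction_manifest(path, base_dir=None) -> list[FractionRecord]:
    """Fraction records from a manifest CSV.

    Columns: fraction, week, dose_path, dvf_path (optional/blank), shift_x,
    shift_y, shift_z, weight.  Relative paths resolve against ``base_dir``
    (default: the manifest's directory).
    """
    path = Path(path)
    base = Path(base_dir) if base_dir is not None else path.parent
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        dose = read_dose_nifti(base / str(row["dose_path"]))
        dvf = None
        if "dvf_path" in row and isinstance(row["dvf_path"], str) and row["dvf_path"]:
            dvf = read_dvf_nifti(base / str(row["dvf_path"]))
        records.append(
            FractionRecord(
                index=int(row["fraction"]),
                week=int(row.get("week", 0)),
                dose=dose,
                dvf=dvf,
                rigid_shift=(
                    float(row.get("shift_x", 0.0)),
                    float(row.get("shift_y", 0.0)),
                    float(row.get("shift_z", 0.0)),
                ),
                n_fractions_represented=int(row["weight"]),
            )
        )
    return records
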