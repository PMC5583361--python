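"""On-disk cohort layout: per-patient NIfTI volumes/masks plus a clinical CSV.

Layout::

    cohort_dir/
      clinical.csv            # patient_id, age, kps, os_days, event
      <patient_id>/T1.nii.gz  T1C.nii.gz  T2.nii.gz  FLAIR.nii.gz  mask.nii.gz

Voxel spacing is carried in the NIfTI affine (diagonal; identity
orientation by the package's coordinate convention).
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from radsurv.phantom import MODALITIES, PatientRecord
from radsurv.preprocess import SubregionMask

CLINICAL_COLUMNS = ["patient_id", "age", "kps", "os_days", "event"]


def _affine(spacing: Sequence[float]) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def write_cohort(records: List[PatientRecord], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        pdir = directory / rec.patient_id
        pdir.mkdir(exist_ok=True)
        aff = _affine(rec.spacing)
        for modality in MODALITIES:
            nib.save(
                nib.Nifti1Image(rec.volumes[modality].astype(np.float32), aff),
                pdir / f"{modality}.nii.gz",
            )
        nib.save(nib.Nifti1Image(rec.mask.labels.astype(np.uint8), aff), pdir / "mask.nii.gz")
        rows.append(
            {
                "patient_id": rec.patient_id,
                "age": rec.age,
                "kps": rec.kps,
                "os_days": rec.os_days,
                "event": rec.event,
            }
        )
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(directory / "clinical.csv", index=False)


def read_cohort(directory) -> List[PatientRecord]:
    directory = Path(directory)
    clinical = pd.read_csv(directory / "clinical.csv")
    records = []
    for _, row in clinical.iterrows():
        pid = str(row["patient_id"])
        pdir = directory / pid
        volumes = {}
        for modality in MODALITIES:
            img = nib.load(pdir / f"{modality}.nii.gz")
            volumes[modality] = np.asarray(img.dataobj, dtype=float)
        mimg = nib.load(pdir / "mask.nii.gz")
        spacing = tuple(float(z) for z in mimg.header.get_zooms()[:3])
        mask = SubregionMask(np.asarray(mimg.dataobj).astype(np.uint8), spacing)
        records.append(
            PatientRecord(
                patient_id=pid,
                volumes=volumes,
                mask=mask,
                age=float(row["age"]),
                kps=int(row["kps"]),
                os_days=float(row["os_days"]),
                event=int(row["event"]),
            )
        )
    return records


def clinical_frame(records: List[PatientRecord]) -> pd.DataFrame:
    """Clinical/survival table indexed by patient id."""
    df = pd.DataFrame(
        {
            "age": [r.age for r in records],
            "kps": [r.kps for r in records],
            "os_days": [r.os_days for r in records],
            "event": [r.event for r in records],
        },
        index=pd.Index([r.patient_id for r in records], name="patient_id"),
    )
    return df
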