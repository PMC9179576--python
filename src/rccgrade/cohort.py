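"""Patient cohort data model, manifest I/O, temporal splitting and descriptive statistics.

A cohort is a list of patients; each patient carries a Fuhrman grade (1-4),
the derived binary label (grades 1-2 -> low = 0, grades 3-4 -> high = 1), an
acquisition year used for temporal splitting, and an ordered stack of 2-D
region-of-interest images. Labels live at the patient level: every image of a
patient inherits the patient's binary label as its observed label. Synthetic
cohorts may additionally carry a hidden per-image ``true_label``; label noise
is one-directional, so a true label can only ever be *lower* than the observed
one (a patient labeled high-grade whose lesions look low-grade).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ImageSample",
    "Patient",
    "Cohort",
    "ManifestError",
    "grade_to_binary",
    "percentage",
    "read_manifest",
    "write_manifest",
    "temporal_split",
    "cohort_stats",
]

MANIFEST_COLUMNS = ["patient_id", "fuhrman_grade", "acquisition_year", "image_path"]


class ManifestError(ValueError):
    """Raised when a manifest fails validation."""


def grade_to_binary(fuhrman_grade: int) -> int:
    """Binary label rule: grades 1-2 are low-grade (0), grades 3-4 high-grade (1)."""
    if fuhrman_grade not in (1, 2, 3, 4):
        raise ManifestError(f"fuhrman_grade must be in 1..4, got {fuhrman_grade!r}")
    return 0 if fuhrman_grade <= 2 else 1


@dataclass
class ImageSample:
    """One 2-D ROI image with its observed (and optionally hidden true) label."""

    patient_id: str
    observed_label: int
    pixel_data: Optional[np.ndarray] = None
    true_label: Optional[int] = None
    image_path: Optional[str] = None
    image_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.observed_label not in (0, 1):
            raise ValueError(f"observed_label must be 0 or 1, got {self.observed_label}")
        if self.true_label is not None:
            if self.true_label not in (0, 1):
                raise ValueError(f"true_label must be 0 or 1, got {self.true_label}")
            if self.true_label > self.observed_label:
                raise ValueError(
                    "label noise is one-directional: true_label may not exceed observed_label"
                )
        if self.pixel_data is not None:
            _validate_pixels(self.pixel_data)

    @property
    def pixels(self) -> np.ndarray:
        """Pixel array, loading lazily from ``image_path`` on first access."""
        if self.pixel_data is None:
            if self.image_path is None:
                raise ValueError("image has neither pixel_data nor image_path")
            arr = np.asarray(Image.open(self.image_path), dtype=np.float32)
            if arr.dtype.kind in "ui" or arr.max() > 1.0:
                arr = arr / 255.0
            self.pixel_data = arr.astype(np.float32)
            _validate_pixels(self.pixel_data)
        return self.pixel_data


def _validate_pixels(arr: np.ndarray) -> None:
    if arr.ndim not in (2, 3):
        raise ValueError(f"pixel_data must be 2-D (H, W) or 3-D (H, W, C), got shape {arr.shape}")
    if arr.ndim == 3 and arr.shape[2] not in (1, 3):
        raise ValueError(f"channel count must be 1 or 3, got {arr.shape[2]}")
    if arr.shape[0] < 8 or arr.shape[1] < 8:
        raise ValueError(f"images must be at least 8x8, got {arr.shape[:2]}")


@dataclass
class Patient:
    """One subject: grade, derived binary label, acquisition year and image stack."""

    patient_id: str
    fuhrman_grade: int
    acquisition_year: int
    images: list[ImageSample] = field(default_factory=list)
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        grade_to_binary(self.fuhrman_grade)  # validates the range
        for img in self.images:
            if img.patient_id != self.patient_id:
                raise ValueError(
                    f"image {img.image_id!r} carries patient_id {img.patient_id!r}, "
                    f"expected {self.patient_id!r}"
                )

    @property
    def binary_label(self) -> int:
        return grade_to_binary(self.fuhrman_grade)

    @property
    def n_images(self) -> int:
        return len(self.images)


@dataclass
class Cohort:
    patients: list[Patient] = field(default_factory=list)
    name: str = "cohort"

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    @property
    def n_images(self) -> int:
        return sum(p.n_images for p in self.patients)

    def images(self) -> list[ImageSample]:
        """All images in patient order."""
        return [img for p in self.patients for img in p.images]

    def has_true_labels(self) -> bool:
        return all(img.true_label is not None for p in self.patients for img in p.images)


def percentage(part: int, whole: int) -> float:
    """Percentage rounded half-up to one decimal (374/592 -> 63.2)."""
    if whole <= 0:
        raise ValueError("percentage base must be positive")
    q = Decimal(100 * part) / Decimal(whole)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def read_manifest(path: str | Path) -> Cohort:
    """Read a cohort manifest (CSV, one row per image; or the JSON alternative).

    Required columns/keys: patient_id, fuhrman_grade, acquisition_year,
    image_path. Optional: true_label (per image), sex (per patient). Image
    files are loaded lazily. Invalid grades raise :class:`ManifestError`
    naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    if path.suffix.lower() == ".json":
        return _read_json_manifest(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path} missing columns: {missing}")
    patients: dict[str, Patient] = {}
    for idx, row in df.iterrows():
        pid = str(row["patient_id"])
        grade = int(row["fuhrman_grade"])
        if grade not in (1, 2, 3, 4):
            raise ManifestError(f"row {idx}: fuhrman_grade must be in 1..4, got {grade}")
        year = int(row["acquisition_year"])
        if pid not in patients:
            sex = row.get("sex")
            patients[pid] = Patient(
                patient_id=pid,
                fuhrman_grade=grade,
                acquisition_year=year,
                sex=None if pd.isna(sex) else str(sex) if sex is not None else None,
            )
        pat = patients[pid]
        if pat.fuhrman_grade != grade or pat.acquisition_year != year:
            raise ManifestError(f"row {idx}: inconsistent grade/year for patient {pid!r}")
        true_label = None
        if "true_label" in df.columns and not pd.isna(row["true_label"]):
            true_label = int(row["true_label"])
        img_path = row["image_path"]
        pat.images.append(
            ImageSample(
                patient_id=pid,
                observed_label=pat.binary_label,
                true_label=true_label,
                image_path=None if pd.isna(img_path) else str(img_path),
                image_id=f"{pid}_{len(pat.images)}",
            )
        )
    cohort = Cohort(patients=list(patients.values()), name=path.stem)
    for p in cohort:
        if p.n_images < 1:
            raise ManifestError(f"patient {p.patient_id!r} has no images")
    return cohort


def _read_json_manifest(path: Path) -> Cohort:
    with open(path) as fh:
        doc = json.load(fh)
    patients = []
    for rec in doc["patients"]:
        grade = int(rec["fuhrman_grade"])
        if grade not in (1, 2, 3, 4):
            raise ManifestError(
                f"patient {rec.get('patient_id')!r}: fuhrman_grade must be in 1..4, got {grade}"
            )
        pid = str(rec["patient_id"])
        pat = Patient(
            patient_id=pid,
            fuhrman_grade=grade,
            acquisition_year=int(rec["acquisition_year"]),
            sex=rec.get("sex"),
        )
        for k, img in enumerate(rec["images"]):
            pat.images.append(
                ImageSample(
                    patient_id=pid,
                    observed_label=pat.binary_label,
                    true_label=img.get("true_label"),
                    image_path=img.get("image_path"),
                    image_id=f"{pid}_{k}",
                )
            )
        patients.append(pat)
    return Cohort(patients=patients, name=doc.get("name", path.stem))


def write_manifest(cohort: Cohort, path: str | Path) -> None:
    """Write a manifest readable by :func:`read_manifest`.

    CSV by default (one row per image, patient fields repeated); a ``.json``
    suffix selects the grouped JSON alternative. Pixel data are not written
    here -- see :func:`rccgrade.synthgen.write_cohort` for materializing
    synthetic images to PNG.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "name": cohort.name,
            "patients": [
                {
                    "patient_id": p.patient_id,
                    "fuhrman_grade": p.fuhrman_grade,
                    "acquisition_year": p.acquisition_year,
                    **({"sex": p.sex} if p.sex is not None else {}),
                    "images": [
                        {
                            **({"image_path": i.image_path} if i.image_path else {}),
                            **({"true_label": i.true_label} if i.true_label is not None else {}),
                        }
                        for i in p.images
                    ],
                }
                for p in cohort
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
        return
    rows = []
    any_true = any(i.true_label is not None for p in cohort for i in p.images)
    any_sex = any(p.sex is not None for p in cohort)
    for p in cohort:
        for img in p.images:
            row = {
                "patient_id": p.patient_id,
                "fuhrman_grade": p.fuhrman_grade,
                "acquisition_year": p.acquisition_year,
                "image_path": img.image_path if img.image_path is not None else "",
            }
            if any_true:
                row["true_label"] = img.true_label
            if any_sex:
                row["sex"] = p.sex
            rows.append(row)
    cols = MANIFEST_COLUMNS + (["true_label"] if any_true else []) + (["sex"] if any_sex else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def temporal_split(cohort: Cohort, cutoff_year: int) -> tuple[Cohort, Cohort]:
    """Split by acquisition year: before the cutoff -> development, the cutoff
    year and later -> validation. Order is preserved within each part; the two
    parts are an exhaustive, disjoint partition for any cutoff."""
    dev = [p for p in cohort if p.acquisition_year < cutoff_year]
    val = [p for p in cohort if p.acquisition_year >= cutoff_year]
    return (
        Cohort(patients=dev, name=f"{cohort.name}-development"),
        Cohort(patients=val, name=f"{cohort.name}-validation"),
    )


def cohort_stats(cohort: Cohort) -> dict:
    """Counts and half-up one-decimal percentages for a cohort.

    Percentages are over the patient count. Includes the binary label split,
    the Fuhrman grade distribution, and sex when present.
    """
    if len(cohort) == 0:
        raise ValueError("cohort_stats of an empty cohort")
    n = len(cohort)
    out: dict = {"name": cohort.name, "n_patients": n, "n_images": cohort.n_images}
    for label, key in ((0, "low_grade"), (1, "high_grade")):
        c = sum(1 for p in cohort if p.binary_label == label)
        out[key] = {"count": c, "percent": percentage(c, n)}
    grades = {}
    for g in (1, 2, 3, 4):
        c = sum(1 for p in cohort if p.fuhrman_grade == g)
        grades[g] = {"count": c, "percent": percentage(c, n)}
    out["fuhrman_grade"] = grades
    if any(p.sex is not None for p in cohort):
        sexes: dict[str, dict] = {}
        for s in sorted({p.sex for p in cohort if p.sex is not None}):
            c = sum(1 for p in cohort if p.sex == s)
            sexes[s] = {"count": c, "percent": percentage(c, n)}
        out["sex"] = sexes
    years = [p.acquisition_year for p in cohort]
    out["year_range"] = (min(years), max(years))
    return out
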