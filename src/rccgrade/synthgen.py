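"""Seeded generator of synthetic ROI-cropped grading cohorts.

The real study data (contrast-enhanced CT tumor crops from a single hospital)
are not publicly available, so this module emulates their structure: a cohort
of patients split by acquisition year, roughly 60/40 low/high-grade, ~10-25
variable-size single-channel images per patient, grade-dependent lesion
appearance, and one-directional label noise (a controllable fraction of
high-labeled patients whose lesions are drawn from the low-grade appearance
distribution).

Appearance model, per image: a Gaussian-textured background with a mild
vertical intensity gradient (an orientation statistic standing in for the
anatomy-driven orientation of real CT crops -- without one, predicting image
rotation is information-free), plus one bright ellipse whose area and internal
speckle heterogeneity increase monotonically with the generating Fuhrman
grade. This is a phantom, not a CT simulation: separable by construction so
desk-scale learning runs are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image

from .cohort import Cohort, ImageSample, Patient, write_manifest

__all__ = ["AppearanceParams", "SynthConfig", "generate_cohort", "corruption_report", "write_cohort"]


@dataclass(frozen=True)
class AppearanceParams:
    """Per-grade lesion geometry and texture knobs.

    ``radius_frac[g]`` is the mean lesion semi-axis as a fraction of the image
    edge for Fuhrman grade g; ``heterogeneity[g]`` the amplitude of the
    intra-lesion speckle. Both increase with grade: high-grade lesions are
    larger and more heterogeneous.
    """

    radius_frac: tuple[float, float, float, float] = (0.20, 0.25, 0.33, 0.40)
    heterogeneity: tuple[float, float, float, float] = (0.04, 0.07, 0.14, 0.20)
    lesion_intensity: float = 0.70
    background_level: float = 0.35
    background_noise: float = 0.06
    gradient_amplitude: float = 0.12  # top-to-bottom intensity drop; orientation cue


@dataclass(frozen=True)
class SynthConfig:
    n_patients: int = 706
    high_fraction: float = 0.391  # 276/706 high-grade overall
    images_per_patient_range: tuple[int, int] = (10, 25)  # targets ~17.7 images/patient
    image_size_range: tuple[int, int] = (24, 96)  # pre-resize edge lengths
    noise_rate_true: float = 0.4
    year_range: tuple[int, int] = (2010, 2019)
    dev_year_cutoff: int = 2018
    dev_fraction: float = 592 / 706  # fraction of patients with pre-cutoff years
    seed: int = 0
    appearance: AppearanceParams = field(default_factory=AppearanceParams)
    p_male: float = 0.63

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0.0 <= self.high_fraction <= 1.0:
            raise ValueError("high_fraction must be in [0, 1]")
        if not 0.0 <= self.noise_rate_true <= 1.0:
            raise ValueError("noise_rate_true must be in [0, 1]")
        for name in ("images_per_patient_range", "image_size_range", "year_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ValueError(f"{name} must be a non-degenerate positive range, got {(lo, hi)}")
        if not self.year_range[0] < self.dev_year_cutoff <= self.year_range[1] + 1:
            raise ValueError("dev_year_cutoff must sit inside year_range")


def _lesion_image(rng: np.random.Generator, edge: int, grade: int, ap: AppearanceParams) -> np.ndarray:
    """One single-channel phantom image for a generating grade (1-4)."""
    g = grade - 1
    yy, xx = np.mgrid[0:edge, 0:edge].astype(np.float32)
    img = ap.background_level + ap.background_noise * rng.standard_normal((edge, edge)).astype(np.float32)
    img += ap.gradient_amplitude * (0.5 - yy / max(edge - 1, 1))

    r = ap.radius_frac[g] * edge * rng.uniform(0.85, 1.15)
    aspect = rng.uniform(0.65, 1.0)
    theta = rng.uniform(0.0, np.pi)
    cy = edge / 2 + rng.uniform(-0.08, 0.08) * edge
    cx = edge / 2 + rng.uniform(-0.08, 0.08) * edge
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    inside = (u / r) ** 2 + (v / (r * aspect)) ** 2 <= 1.0

    lesion = np.full((edge, edge), ap.lesion_intensity, dtype=np.float32)
    het = ap.heterogeneity[g]
    if het > 0:
        # multi-scale speckle: coarse blobs + fine grain
        coarse = rng.standard_normal((max(edge // 8, 2),) * 2).astype(np.float32)
        coarse = np.asarray(
            Image.fromarray(coarse).resize((edge, edge), Image.BILINEAR), dtype=np.float32
        )
        fine = rng.standard_normal((edge, edge)).astype(np.float32)
        lesion += het * (0.7 * coarse + 0.3 * fine)
    img = np.where(inside, lesion, img)
    return np.clip(img, 0.0, 1.0)


def generate_cohort(config: SynthConfig) -> Cohort:
    """Deterministically generate an in-memory synthetic cohort.

    High-grade patients receive Fuhrman grade 3 or 4, low-grade 1 or 2. A
    ``noise_rate_true`` Bernoulli fraction of high-labeled patients are
    corrupted: their observed label stays high but every image is drawn from
    a low-grade appearance distribution and tagged ``true_label = 0``.
    Low-labeled patients are never corrupted.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_dev = int(round(n * config.dev_fraction))
    ap = config.appearance

    patients = []
    for i in range(n):
        pid = f"SYN{i:04d}"
        is_high = rng.random() < config.high_fraction
        grade = int(rng.integers(3, 5)) if is_high else int(rng.integers(1, 3))
        observed = 1 if is_high else 0
        corrupted = bool(is_high and rng.random() < config.noise_rate_true)
        # corrupted high-grade patients look like a (random) low grade
        appearance_grade = int(rng.integers(1, 3)) if corrupted else grade
        true_label = 0 if corrupted else observed
        if i < n_dev:
            year = int(rng.integers(config.year_range[0], config.dev_year_cutoff))
        else:
            year = int(rng.integers(config.dev_year_cutoff, config.year_range[1] + 1))
        sex = "M" if rng.random() < config.p_male else "F"
        m = int(rng.integers(config.images_per_patient_range[0], config.images_per_patient_range[1] + 1))
        pat = Patient(patient_id=pid, fuhrman_grade=grade, acquisition_year=year, sex=sex)
        for k in range(m):
            edge = int(rng.integers(config.image_size_range[0], config.image_size_range[1] + 1))
            pat.images.append(
                ImageSample(
                    patient_id=pid,
                    observed_label=observed,
                    true_label=true_label,
                    pixel_data=_lesion_image(rng, edge, appearance_grade, ap),
                    image_id=f"{pid}_{k}",
                )
            )
        patients.append(pat)
    return Cohort(patients=patients, name=f"synthetic-seed{config.seed}")


def corruption_report(cohort: Cohort) -> dict:
    """Realized one-directional label-noise rate of a synthetic cohort.

    Returns the corrupted fraction among high-labeled patients (``None`` when
    the cohort has no high-labeled patients) and confirms zero corruption
    among low-labeled patients. A patient counts as corrupted when any of its
    images has ``true_label < observed_label``; the generator corrupts whole
    patients, so this matches the per-image picture.
    """
    if not cohort.has_true_labels():
        raise ValueError("corruption_report requires a cohort with true_labels on every image")
    n_high = n_high_corrupted = n_low = n_low_corrupted = 0
    for p in cohort:
        corrupted = any(i.true_label < i.observed_label for i in p.images)
        if p.binary_label == 1:
            n_high += 1
            n_high_corrupted += corrupted
        else:
            n_low += 1
            n_low_corrupted += corrupted
    return {
        "n_high_labeled": n_high,
        "n_high_corrupted": n_high_corrupted,
        "realized_noise_rate": (n_high_corrupted / n_high) if n_high else None,
        "n_low_labeled": n_low,
        "n_low_corrupted": n_low_corrupted,
    }


def write_cohort(cohort: Cohort, directory: str | Path, manifest_name: str = "manifest.csv") -> Path:
    """Materialize a cohort to disk: 8-bit grayscale/RGB PNGs plus a manifest."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    for p in cohort:
        for img in p.images:
            rel = f"images/{img.image_id}.png"
            arr = np.clip(img.pixels * 255.0 + 0.5, 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(directory / rel)
            img.image_path = str(directory / rel)
    manifest_path = directory / manifest_name
    write_manifest(cohort, manifest_path)
    return manifest_path


def mean_lesion_area_by_label(cohort: Cohort, threshold: float = 0.55) -> dict:
    """Trivial separability statistic: mean bright-pixel fraction per true-label group."""
    groups: dict[int, list[float]] = {0: [], 1: []}
    for p in cohort:
        for img in p.images:
            lab = img.true_label if img.true_label is not None else img.observed_label
            groups[lab].append(float((img.pixels > threshold).mean()))
    out = {}
    for lab, vals in groups.items():
        v = np.asarray(vals)
        out[lab] = {"mean": float(v.mean()) if len(v) else None,
                    "sd": float(v.std()) if len(v) else None,
                    "n": len(v)}
    return out
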