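import numpy as np
import pytest

from rccgrade.cohort import Cohort, ImageSample, Patient


def make_patient(pid, grade, year, n_images=2, edge=16, seed=0, true_label=None, sex=None):
    rng = np.random.default_rng(seed)
    label = 0 if grade <= 2 else 1
    pat = Patient(patient_id=pid, fuhrman_grade=grade, acquisition_year=year, sex=sex)
    for k in range(n_images):
        pat.images.append(
            ImageSample(
                patient_id=pid,
                observed_label=label,
                true_label=true_label if true_label is not None else None,
                pixel_data=rng.random((edge, edge)).astype(np.float32),
                image_id=f"{pid}_{k}",
            )
        )
    return pat


@pytest.fixture
def tiny_cohort():
    """Four patients, two per class, 16 px single-channel images."""
    return Cohort(
        patients=[
            make_patient("P1", 1, 2015, seed=1),
            make_patient("P2", 2, 2016, seed=2),
            make_patient("P3", 3, 2018, seed=3),
            make_patient("P4", 4, 2019, seed=4),
        ],
        name="tiny",
    )
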