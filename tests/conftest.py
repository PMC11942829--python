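"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

from renodenoise import dose, phantom
from renodenoise.study_io import StudyRecord


def make_records(n_studies: int, image_size: int = 32, n_frames: int = 30,
                 seed0: int = 0):
    """A small synthetic cohort with evenly spread ages and ground-truth ROIs."""
    records = []
    for i in range(n_studies):
        age = float((i * 17) // max(n_studies - 1, 1))
        spec = phantom.make_phantom_spec(seed=seed0 + i, patient_age_years=age,
                                         image_size=image_size)
        study = phantom.sample_study(spec, count_scale=1.0, n_frames=n_frames,
                                     study_id=f"study_{i:03d}")
        records.append(StudyRecord(study=study,
                                   rois=phantom.ground_truth_rois(spec)))
    return records


@pytest.fixture(scope="session")
def small_records():
    return make_records(8)


@pytest.fixture(scope="session")
def small_pairs(small_records):
    pairs, _ = dose.build_dataset(small_records)
    return pairs


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
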