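import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ezloc.core_data import (
    ALL_ROIS,
    COHORT_COLUMNS,
    LESION_FEATURES,
    CohortTable,
    FeatureName,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_cohort_frame(
    n_patients=1,
    raters=("R1",),
    seizure_free=None,
    ez_roi_index=(0,),
):
    """All-features-false cohort frame; EZ at the given ROI indices of
    every seizure-free patient."""
    if seizure_free is None:
        seizure_free = [True] * n_patients
    rows = []
    for p in range(n_patients):
        pid = f"P{p + 1:03d}"
        for rater in raters:
            for i, roi in enumerate(ALL_ROIS):
                row = {
                    "patient_id": pid,
                    "rater_id": rater,
                    "hemisphere": roi.hemisphere.value,
                    "region": roi.region.value,
                    "ez": seizure_free[p] and i in ez_roi_index,
                    "seizure_free": seizure_free[p],
                }
                for f in FeatureName:
                    row[f.value] = False
                rows.append(row)
    return pd.DataFrame(rows)[COHORT_COLUMNS]


def set_features(frame, patient_id, roi_index, features, rater_id=None):
    """Switch on features at one ROI (by canonical index) of one patient,
    for one rater or all raters, in place."""
    roi = ALL_ROIS[roi_index]
    mask = (
        (frame["patient_id"] == patient_id)
        & (frame["hemisphere"] == roi.hemisphere.value)
        & (frame["region"] == roi.region.value)
    )
    if rater_id is not None:
        mask &= frame["rater_id"] == rater_id
    for f in features:
        frame.loc[mask, FeatureName(f).value] = True
    return frame


@pytest.fixture
def minimal_frame():
    return make_cohort_frame()


@pytest.fixture
def minimal_cohort(minimal_frame):
    return CohortTable.from_frame(minimal_frame)


@pytest.fixture
def two_patient_cohort():
    """Hand-built fixture: patient A carries tuber+calcification only in
    its EZ ROI; patient B carries them in one EZ and one non-EZ ROI."""
    frame = make_cohort_frame(n_patients=2)
    set_features(frame, "P001", 0, ["tuber", "calcification"])
    set_features(frame, "P002", 0, ["tuber", "calcification"])
    set_features(frame, "P002", 5, ["tuber", "calcification"])
    return CohortTable.from_frame(frame)


@pytest.fixture
def cohort_builder():
    return make_cohort_frame


def random_small_cohort(seed, n_patients=10):
    """A noisy random cohort for cross-checking search implementations."""
    from ezloc.synthetic import SimulationConfig, generate_cohort

    cfg = SimulationConfig(
        n_patients=n_patients,
        seed=seed,
        p_seizure_free=1.0,
    )
    return generate_cohort(cfg).cohort
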