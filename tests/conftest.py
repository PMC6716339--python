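import numpy as np
import pandas as pd
import pytest

from wearval.containers import CountSeries, Subject
from wearval.preprocess import WearMask
from wearval.synthetic import ProfileConfig, simulate_profile, simulate_subjects


@pytest.fixture
def subject():
    return Subject("S001", height_cm=175.0, weight_kg=75.0, age_y=30.0, sex="male")


@pytest.fixture
def subjects_small():
    return simulate_subjects(6, seed=42)


@pytest.fixture
def profile(subject):
    return simulate_profile(subject, ProfileConfig(), seed=7)


def make_series(axis1, epoch=60, axis2=None, axis3=None, steps=None,
                subject_id="S001", device="dev", start="2018-05-01 00:00:00"):
    return CountSeries(
        subject_id=subject_id, device=device, start_time=pd.Timestamp(start),
        epoch_length=epoch, axis1=np.asarray(axis1, dtype=float),
        axis2=None if axis2 is None else np.asarray(axis2, dtype=float),
        axis3=None if axis3 is None else np.asarray(axis3, dtype=float),
        steps=None if steps is None else np.asarray(steps, dtype=float),
    )


def all_worn_mask(n, start="2018-05-01 00:00:00"):
    return WearMask(np.ones(n, dtype=bool), pd.Timestamp(start))


@pytest.fixture
def make_series_fixture():
    return make_series
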