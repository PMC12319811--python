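import numpy as np
import pandas as pd
import pytest

from dyadsync import RoiTimeSeries, SyntheticConfig, generate_dyad_timeseries


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale synthetic dataset reused by read-only tests."""
    cfg = SyntheticConfig(
        n_couples=8,
        n_rois=6,
        voxels_per_roi=20,
        n_trs=60,
        n_events=4,
        n_clips=4,
        seed=11,
    )
    return generate_dyad_timeseries(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_ts(data, subject_id="s1", roi_id=1):
    return RoiTimeSeries(subject_id=subject_id, roi_id=roi_id, data=np.asarray(data, float))


@pytest.fixture
def couple_table():
    return pd.DataFrame(
        {
            "dyad_id": ["d1", "d2", "d3"],
            "male_id": ["m1", "m2", "m3"],
            "female_id": ["f1", "f2", "f3"],
            "dyad_class": ["couple_high", "couple_low", "couple_high"],
            "cmqi_score": [75.0, 50.0, 65.0],
            "marriage_duration": [4.0, 10.0, 2.0],
        }
    )
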