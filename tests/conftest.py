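import numpy as np
import pytest

from dnecpm import MotionParams, RoiTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_ts(data, tr=2.0, subject_id="sub-000"):
    data = np.asarray(data, dtype=float)
    return RoiTimeSeries(subject_id=subject_id, data=data, tr_seconds=tr,
                         node_ids=[f"n{i}" for i in range(data.shape[0])])


@pytest.fixture
def random_ts(rng):
    return make_ts(rng.standard_normal((6, 120)))


@pytest.fixture
def zero_motion():
    return MotionParams(subject_id="sub-000", data=np.zeros((120, 6)))
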