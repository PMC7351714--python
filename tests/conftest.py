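import numpy as np
import pytest

from ahecast.records import VitalsRecord


def make_record(map_series, hr=80.0, spo2=97.0, patient_id="p0") -> VitalsRecord:
    """A record with an explicit MAP series and constant HR/SpO2."""
    map_series = np.asarray(map_series, dtype=float)
    n = len(map_series)
    return VitalsRecord(
        patient_id=patient_id,
        map_series=map_series,
        hr_series=np.full(n, float(hr)),
        spo2_series=np.full(n, float(spo2)),
    )


@pytest.fixture
def flat_record():
    """A 300-minute record with constant MAP 90."""
    return make_record(np.full(300, 90.0))


@pytest.fixture
def step_drop_record():
    """MAP 100 for 120 min, then an abrupt sustained 70 (no noise)."""
    series = np.concatenate([np.full(120, 100.0), np.full(120, 70.0)])
    return make_record(series)
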