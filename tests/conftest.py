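import numpy as np
import pytest

from itvmargin.metrics import FractionRecord


def make_record(pid="P01", fraction=1, applied=(0, 0, 0), clipbox=(0, 0, 0), amplitude=(2, 10, 5)):
    return FractionRecord(
        patient_id=pid,
        fraction=fraction,
        applied_shift_mm=np.asarray(applied, float),
        clipbox_correction_mm=np.asarray(clipbox, float),
        amplitude_mm=np.asarray(amplitude, float),
    )


@pytest.fixture
def two_patient_records():
    """Hand-built 2-patient, 3-fraction cohort with known deltas.

    Patient P01: baseline shifts (0,1,0), (0,-2,1), (1,0,0) ->
    deltas (first minus later) f2 = (0,3,-1), f3 = (-1,1,0).
    Amplitudes 10/12.5/9 SI -> amplitude deltas f2 = +2.5, f3 = -1 on SI.
    """
    return [
        make_record("P01", 1, applied=(0, 1, 0), clipbox=(0, 0, 0), amplitude=(2, 10, 5)),
        make_record("P01", 2, applied=(1, -1, 1), clipbox=(1, 1, 0), amplitude=(2, 12.5, 5)),
        make_record("P01", 3, applied=(2, 0, 0), clipbox=(1, 0, 0), amplitude=(3, 9, 4)),
        make_record("P02", 1, applied=(0, 0, 0), clipbox=(0, 0, 0), amplitude=(1, 8, 3)),
        make_record("P02", 2, applied=(0, -3, 0), clipbox=(0, 2, 0), amplitude=(1, 8, 3)),
        make_record("P02", 3, applied=(0, 0, 0), clipbox=(0, 0, 0), amplitude=(2, 6, 3)),
    ]
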