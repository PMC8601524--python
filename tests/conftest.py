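import numpy as np
import pytest

from prrt_hemtox.grading import LabSeries, TreatmentCourse, load_default_rules
from prrt_hemtox.volumes import SUVVolume


@pytest.fixture(scope="session")
def rules():
    return load_default_rules()


@pytest.fixture()
def uniform_volume():
    """16^3 grid at 4 mm isotropic spacing, SUV 3.0 everywhere."""
    data = np.full((16, 16, 16), 3.0)
    return SUVVolume(data, (4.0, 4.0, 4.0), {"all": np.ones((16, 16, 16), bool)})


def make_series(patient_id="P1", sex="female", **param_records):
    """LabSeries from keyword lists of (day, value); units are the defaults."""
    units = {"haemoglobin": "mmol/L", "leucocytes": "1e9/L", "neutrophils": "1e9/L", "platelets": "1e9/L"}
    records = {p: [(d, v, units[p]) for d, v in recs] for p, recs in param_records.items()}
    return LabSeries(patient_id=patient_id, records=records, sex=sex)


def standard_course(patient_id="P1", n=4, interval=70.0, activity=7.4):
    return TreatmentCourse(patient_id=patient_id, cycles=[(i + 1, i * interval, activity) for i in range(n)])


@pytest.fixture()
def series_factory():
    return make_series


@pytest.fixture()
def course_factory():
    return standard_course
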