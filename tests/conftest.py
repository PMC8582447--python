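import numpy as np
import pytest

from rionntcp.cohort import Cohort, PatientRecord
from rionntcp.simulate import SimulationConfig, generate_cohort

_DEFAULTS = dict(
    institution="PSI",
    tumor_type="chordoma",
    age=50.0,
    sex="F",
    hypertension="no",
    n_surgeries=1,
    gtv_volume=25.0,
    tumor_involvement="no",
    prescription_dose=74.0,
    proton_dose=74.0,
    photon_dose=0.0,
    optic_dmin=5.0,
    optic_dmean=30.0,
    optic_dmax=60.0,
    optic_d1=55.0,
    optic_d99=10.0,
    followup_months=70.0,
    rion_grade=0,
    modality_protons_only=True,
    modality_pbs=True,
)


def make_record(patient_id: str, **overrides) -> PatientRecord:
    kwargs = dict(_DEFAULTS)
    kwargs.update(overrides)
    return PatientRecord(patient_id=patient_id, **kwargs)


@pytest.fixture
def toy_cohort() -> Cohort:
    """Ten valid records, two with missing hypertension, two events."""
    recs = []
    for i in range(10):
        recs.append(make_record(
            f"P{i:03d}",
            age=30.0 + 4 * i,
            sex="F" if i < 6 else "M",
            hypertension=None if i in (3, 7) else ("yes" if i % 2 else "no"),
            rion_grade=4 if i == 9 else (1 if i == 0 else 0),
            institution="PSI" if i < 5 else "CPO",
            tumor_type="chordoma" if i < 5 else "chondrosarcoma",
            modality_pbs=i < 5,
        ))
    return Cohort(recs, provenance="toy")


@pytest.fixture(scope="session")
def sim_cohort() -> Cohort:
    """A moderately sized synthetic cohort under the default ground truth."""
    return generate_cohort(SimulationConfig(n=2000, seed=20260923))
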