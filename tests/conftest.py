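import io

import numpy as np
import pytest

import octdecay as od
from octdecay.layers import LayerName

TIDY_HEADER = "patient_id,eye,group,days_since_onset,layer,sector,thickness_um,qc_pass\n"


def tidy_csv(rows: list[str]) -> io.StringIO:
    return io.StringIO(TIDY_HEADER + "\n".join(rows) + "\n")


@pytest.fixture
def two_row_csv() -> io.StringIO:
    return tidy_csv(
        [
            "P001,OD,CRAO,38,GCL,RING3_MEAN,31.2,True",
            "C001,OS,CONTROL,0,GCL,RING3_MEAN,47.9,True",
        ]
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    cohort, truth = od.generate_cohort(od.SyntheticConfig(seed=1234))
    return cohort, truth


@pytest.fixture(scope="session")
def gcl_printed_fit():
    """Decay fit of the published untreated GCL column (day-0 baseline included)."""
    from octdecay.datasets import no_drug_points

    return od.fit_decay(no_drug_points(LayerName.GCL, include_day0=True))


def noiseless_points(params: od.DecayParams, days) -> np.ndarray:
    days = np.asarray(days, dtype=float)
    return np.column_stack([days, od.predict_thickness(params, days)])
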