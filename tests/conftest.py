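import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from seroburden import MeasurementMatrix, SampleSheet, make_table_fixture
from seroburden.io import CONCENTRATION

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        # read-only fixtures shared across generated examples
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pea_table():
    return make_table_fixture("pea")


@pytest.fixture(scope="session")
def qka_table():
    return make_table_fixture("qka")


@pytest.fixture
def small_sheet():
    """2 patients (pre/post) + 1 control with duplicate aliquots."""
    rows = pd.DataFrame([
        ("P1_pre", "P1", "patient", "pre", 1),
        ("P1_post", "P1", "patient", "post", 1),
        ("P2_pre", "P2", "patient", "pre", 1),
        ("P2_post", "P2", "patient", "post", 1),
        ("C1_r1", "C1", "control", "none", 1),
        ("C1_r2", "C1", "control", "none", 2),
    ], columns=["sample_id", "subject_id", "role", "timepoint", "replicate_id"])
    return SampleSheet(rows=rows)


@pytest.fixture
def small_matrix(small_sheet):
    """Concentration matrix aligned with small_sheet; known ratios."""
    samples = list(small_sheet.rows["sample_id"])
    values = pd.DataFrame(
        [[40.0, 10.0, 12.0, 12.0, 5.0, 5.0],      # FD 4 / 1
         [9.0, 3.0, 8.0, 2.0, 2.0, 6.0],          # FD 3 / 4, control 3x
         [100.0, 100.0, 50.0, 25.0, 30.0, 33.0]], # FD 1 / 2
        index=["PROT_A", "PROT_B", "PROT_C"], columns=samples,
    )
    return MeasurementMatrix(
        platform_id="toy", scale=CONCENTRATION, units="pg/mL",
        values=values, lld=pd.Series(1.0, index=values.index),
    )
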