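import io

import pytest
from hypothesis import HealthCheck, settings

from comorbnet import ClaimsTable, parse_claims

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


SMALL_CLAIMS_CSV = """\
patient_id,service_date,dx1,dx2,dx3,age,sex
P1,2024-03-01,J45.909,E78.5,,44,F
P1,2024-11-20,J45.909,,,44,F
P2,2024-01-15,I10,E78.5,,61,M
P2,2023-06-02,I10,,,60,M
P3,2024-07-09,F41.9,J45.909,,29,F
"""


@pytest.fixture
def small_claims_csv() -> str:
    return SMALL_CLAIMS_CSV


@pytest.fixture
def small_claims() -> ClaimsTable:
    table, _ = parse_claims(io.StringIO(SMALL_CLAIMS_CSV))
    return table
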