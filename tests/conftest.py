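from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from ltp_epimap.epitopes import load_reported_epitopes

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Real-accession FASTA fixture (query + allergenic + 15-LTP panels). Created by
#: scripts/fetch_ncbi_accessions.py, which needs network access to NCBI; the
#: accession-bound acceptance checks fail with an explanatory message without it.
ACCESSION_FASTA = Path(__file__).parent / "fixtures" / "ncbi_ltp_accessions.fasta"


@pytest.fixture(scope="session")
def table2_by_parent() -> dict:
    regions: dict[str, list] = {}
    for region in load_reported_epitopes("table2"):
        regions.setdefault(region.parent_id, []).append(region)
    return regions


@pytest.fixture(scope="session")
def validated_peach() -> list:
    return load_reported_epitopes("validated")
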