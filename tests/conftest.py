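import pytest

from magescreen.hla import builtin_pgroup_table, DEFAULT_RULES, parse_allele
from magescreen.ihc import StainingRecord


@pytest.fixture(scope="session")
def pgroups():
    return builtin_pgroup_table()


@pytest.fixture(scope="session")
def rules():
    return DEFAULT_RULES


@pytest.fixture
def allele():
    """Shorthand parser for readable pair construction in tests."""
    return parse_allele


def make_record(
    sample_id="S1",
    patient_id="P1",
    tumor_type="SyS",
    p_score=50.0,
    split23=(0.6, 0.4),
    **kw,
):
    """Staining record with a requested P score, remainder on intensity 0."""
    pct2 = split23[0] * p_score
    pct3 = split23[1] * p_score
    return StainingRecord(
        sample_id=sample_id,
        patient_id=patient_id,
        tumor_type=tumor_type,
        pct_intensity=(100.0 - p_score, 0.0, pct2, pct3),
        **kw,
    )
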