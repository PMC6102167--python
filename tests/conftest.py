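import pytest
from hypothesis import HealthCheck, settings

from polypharm.fixtures import FixtureSpec, make_source_tables
from polypharm.ingest import read_qualitative_table, read_quantitative_table
from polypharm.query import build_database

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def source_tables(tmp_path_factory):
    """Synthetic evidence tables with independently computed ground truth."""
    outdir = tmp_path_factory.mktemp("tables")
    return make_source_tables(FixtureSpec(seed=7), outdir)


@pytest.fixture(scope="session")
def records(source_tables):
    quant, _ = read_quantitative_table(source_tables.quantitative_path, "chembl-like")
    qual, _ = read_qualitative_table(source_tables.qualitative_path, "curated-like")
    return quant + qual


@pytest.fixture(scope="session")
def db(records):
    """The full database built from the synthetic evidence stream."""
    return build_database(records)
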