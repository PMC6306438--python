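import pytest
from hypothesis import HealthCheck, settings

from summarymr import datasets, select_instruments
from summarymr.datasets import write_trait_tables

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def t2dm_harmonized():
    """All five CRP/T2DM fixture variants, harmonized."""
    return datasets.crp_t2dm_harmonized()


@pytest.fixture(scope="session")
def t2dm_instruments(t2dm_harmonized):
    """The four instruments surviving selection (rs4420638 removed)."""
    kept, _ = select_instruments(t2dm_harmonized)
    return kept


@pytest.fixture(scope="session")
def t1dm_harmonized():
    """The three CRP/T1DM fixture variants, harmonized."""
    return datasets.crp_t1dm_harmonized()


@pytest.fixture
def t2dm_trait_files(tmp_path):
    """Per-trait exposure/outcome TSVs for the T2DM fixture."""
    exp, out = tmp_path / "crp.tsv", tmp_path / "t2dm.tsv"
    write_trait_tables("t2dm", exp, out)
    return exp, out


@pytest.fixture
def t1dm_trait_files(tmp_path):
    exp, out = tmp_path / "crp.tsv", tmp_path / "t1dm.tsv"
    write_trait_tables("t1dm", exp, out)
    return exp, out
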