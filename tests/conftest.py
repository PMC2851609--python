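import pytest
from hypothesis import HealthCheck, settings

from genenorm.fixtures import fixture_tables
from genenorm.text import SymbolTables

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tables() -> SymbolTables:
    """Bundled symbol tables (Greek names + stopwords, empty bio-lexicon)."""
    return SymbolTables.default()


@pytest.fixture(scope="session")
def fx_tables() -> SymbolTables:
    """Symbol tables with the fixture bio-lexicon spanning all filter tiers."""
    return fixture_tables()
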