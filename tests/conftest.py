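import pytest

from satmut import fixture_genotype_table, load_ma_marker_panel


@pytest.fixture(scope="session")
def panel():
    """(markers, calls) of the packaged 41-marker MA panel."""
    return load_ma_marker_panel()


@pytest.fixture(scope="session")
def panel_table():
    """Genotype table realizing the packaged panel (82 lines, 142 generations)."""
    return fixture_genotype_table()
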