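import pytest

from scombkey.synthetic_data import (
    SimConfig,
    generate_query_set,
    generate_reference_panel,
    generate_second_marker_panel,
)


@pytest.fixture(scope="session")
def default_panel():
    """Default synthetic panel (130 refs, 13 species, 612 columns)."""
    return generate_reference_panel(SimConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_study():
    """The full noiseless study setting: panels for both markers + 188 queries."""
    cfg = SimConfig(seed=23, error_rate=0.0)
    panel = generate_reference_panel(cfg)
    panel2 = generate_second_marker_panel(cfg)
    queries = generate_query_set(cfg, panel, panel2)
    return cfg, panel, panel2, queries
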