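import pytest

from aligncount import Family, f_table, g_table, h_table

GRID = 12  # shared window for cross-route table comparisons


@pytest.fixture(scope="session")
def tables():
    """DP ground-truth tables for all three families on the shared window."""
    return {
        Family.F: f_table(GRID, GRID),
        Family.H: h_table(GRID, GRID),
        Family.G: g_table(GRID, GRID),
    }
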