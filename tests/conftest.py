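import pytest

from logicfate import build_g1s_model, fate_table


@pytest.fixture(scope="session")
def g1s():
    return build_g1s_model()


@pytest.fixture(scope="session")
def g1s_graph(g1s):
    return g1s.regulatory_graph()


@pytest.fixture(scope="session")
def wt_rows(g1s):
    """Wild-type fate table rows, one per (SSB, DSB) combination."""
    return fate_table(g1s)


@pytest.fixture(scope="session")
def wt_states(wt_rows):
    """(ssb, dsb) -> the unique wild-type stable state."""
    return {(r.ssb, r.dsb): r.states[0] for r in wt_rows}
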