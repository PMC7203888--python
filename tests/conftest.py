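import pytest
from hypothesis import strategies as st

from labourpath import DEFAULT_PROTOCOL, PathCountTable
from labourpath.fixtures import load_fixture


@pytest.fixture(scope="session")
def bcm():
    return load_fixture("table7_bcm")


@pytest.fixture(scope="session")
def acm():
    return load_fixture("table7_acm")


def path_count_tables(n_max: int = 3, min_total: int = 1, max_count: int = 200):
    """Hypothesis strategy for random non-empty path-count tables."""

    @st.composite
    def build(draw):
        n = draw(st.integers(1, n_max))
        labels = tuple(f"I{i}" for i in range(n))
        from labourpath import InterventionProtocol, enumerate_paths

        protocol = InterventionProtocol(labels)
        counts = {}
        for p in enumerate_paths(protocol):
            counts[tuple(p.flags)] = draw(st.integers(0, max_count))
        table = PathCountTable(protocol, counts)
        if table.N < min_total:
            counts[(0,) * n] = counts.get((0,) * n, 0) + min_total
            table = PathCountTable(protocol, counts)
        return table

    return build()
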