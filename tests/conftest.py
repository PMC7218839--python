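import numpy as np
import pytest

from scanspc import QuarterlySeries

# Study design constants used across the suite: in-control and
# out-of-control non-indicated scan rates, patients per quarter, monitoring
# horizon (5 years of quarters), and the common false-signal budget.
DESIGN = {
    "p0": 0.059,
    "p1": 0.114,
    "n_per_quarter": 26,
    "horizon_T": 20,
    "target": 0.10,
}


@pytest.fixture(scope="session")
def design():
    return dict(DESIGN)


def make_series(x, n=26, **kwargs):
    """Build a QuarterlySeries from event counts with constant volume."""
    x = np.asarray(x, dtype=np.int64)
    return QuarterlySeries(n=np.full(x.size, n, dtype=np.int64), x=x, **kwargs)


@pytest.fixture
def series_factory():
    return make_series
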