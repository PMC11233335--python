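import numpy as np
import pytest

from emolba.lba import AccumulatorParams, CellParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def typical_cell():
    """Parameters in the plausible range for emotion-report data."""
    return CellParams.make(A=2.0, B=2.0, mean_v_normative=3.0, mean_v_aberrant=0.5)


@pytest.fixture
def typical_acc():
    return AccumulatorParams(A=2.0, B=2.0, mean_v=2.0, sv=1.0, t0=0.3)


def lba_param_grid():
    """>= 20 parameter sets spanning the plausible region (used by both the
    oracle-equivalence and normalization checks)."""
    sets = []
    for A in (0.5, 2.0):
        for B in (1.0, 2.0):
            for vn in (1.0, 2.5):
                for va in (0.0, 0.742):
                    sets.append(dict(A=A, B=B, vn=vn, va=va, sv=1.0, t0=0.3))
    for extra in (
        dict(A=1e-9, B=1.0, vn=2.0, va=0.5, sv=1.0, t0=0.2),   # degenerate start
        dict(A=3.0, B=0.5, vn=3.172, va=0.017, sv=1.0, t0=0.4),
        dict(A=2.0, B=2.0, vn=2.0, va=0.5, sv=0.5, t0=0.3),
        dict(A=2.0, B=3.0, vn=1.5, va=-0.5, sv=1.0, t0=0.3),   # negative mean drift
    ):
        sets.append(extra)
    return sets
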