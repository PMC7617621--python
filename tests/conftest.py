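import pytest

from hetwalk import (
    HeterogeneitySet,
    LatticeSpec,
    homogeneous_propagator_gf,
    make_antibarrier,
    make_barrier,
    make_long_range,
    make_slippery,
    make_sticky,
)


@pytest.fixture(scope="session")
def spec_2d_q02():
    """The 10x10 reflecting lattice with q = (0.2, 0.2) used throughout the
    2D examples (bulk jump 0.05, bulk stay 0.8)."""
    return LatticeSpec((10, 10), (0.2, 0.2))


@pytest.fixture(scope="session")
def gf_2d_q02(spec_2d_q02):
    return homogeneous_propagator_gf(spec_2d_q02)


@pytest.fixture(scope="session")
def spec_1d_q23():
    """1D reflecting segment, q = 2/3, 15 sites (quasi-1D barrier studies)."""
    return LatticeSpec((15,), (2.0 / 3.0,))


def _mixed_defect_set(spec):
    """One set exercising all five heterogeneity classes at once."""
    hs = HeterogeneitySet(spec)
    hs.add(make_barrier(spec, (5, 5), (5, 6), 1.0, 1.0))
    hs.add(make_barrier(spec, (4, 5), (4, 6), 0.5, 0.7))
    hs.add(make_antibarrier(spec, (7, 2), (7, 3), 0.4, 0.6))
    hs.add(make_long_range(spec, (2, 2), (9, 9), 0.5, 0.5))
    hs.add(make_sticky(spec, (8, 8), 0.25))
    hs.add(make_slippery(spec, (3, 8), 0.5))
    return hs


@pytest.fixture()
def mixed_set(spec_2d_q02):
    return _mixed_defect_set(spec_2d_q02)
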