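"""Shared fixtures: tiny deterministic communities and the study pools.

Everything is generated at test time; expensive objects are session-scoped.
"""

import numpy as np
import pytest

from neutralmig import (
    build_ranked_logseries,
    make_fixtures,
    metacommunity_from_alpha,
)


@pytest.fixture(scope="session")
def small_meta():
    """A small logseries pool (10,000 individuals, 50 species)."""
    return build_ranked_logseries(10_000, 50)


@pytest.fixture(scope="session")
def mid_meta():
    """A mid-sized, diverse pool for reduced-scale simulation tests."""
    return build_ranked_logseries(1_000_000, 2_000)


@pytest.fixture(scope="session")
def mc_spatial():
    """The lattice-study pool: 5.5 million trees, Fisher's alpha 272."""
    return metacommunity_from_alpha(5_500_000, 272.0)


@pytest.fixture(scope="session")
def mc_low():
    """The low-diversity regional pool (Guiana-shield-like)."""
    return build_ranked_logseries(20_191_600_511, 4_582)


@pytest.fixture(scope="session")
def mc_high():
    """The high-diversity regional pool (western-Amazon-like)."""
    return build_ranked_logseries(5_611_001_426, 6_834)


@pytest.fixture(scope="session")
def fixtures():
    """The deterministic tiny assets from the io module (seed 0)."""
    return make_fixtures(seed=0)
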