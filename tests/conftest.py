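"""Shared fixtures: toy components and synthetic sigma-profiles."""

import numpy as np
import pytest

from cosmopr.eos import PureComponent
from cosmopr.fixtures import synthetic_sigma_profile, toy_components


@pytest.fixture(scope="session")
def hexane():
    return PureComponent.from_critical("hexane", 507.6, 3.025e6, 0.301)


@pytest.fixture(scope="session")
def water():
    return PureComponent.from_critical("water", 647.1, 22.064e6, 0.345)


@pytest.fixture(scope="session")
def toy_pairs():
    """Six deterministic (component, profile) pairs."""
    return toy_components(seed=42, n=6)


@pytest.fixture(scope="session")
def alkane_profile():
    return synthetic_sigma_profile(11, "alkane", total_area=150.0, name="alk")


@pytest.fixture(scope="session")
def hydroxyl_profile():
    return synthetic_sigma_profile(12, "hydroxyl", total_area=60.0, name="hyd")


@pytest.fixture(scope="session")
def generic_profile():
    return synthetic_sigma_profile(13, "generic", total_area=120.0, name="gen")
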