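import numpy as np
import pytest

from bdtem.geometry import make_supertile_spec, plan_montage


@pytest.fixture(scope="session")
def paper_spec():
    """The 6000-px 3x3 supertile with 15% subtile overlap."""
    return make_supertile_spec(6000, 3, 3, 0.15)


@pytest.fixture(scope="session")
def plan_3nm(paper_spec):
    """1 mm^2 section at 3 nm/pixel, 600-px supertile overlap."""
    return plan_montage(1e6, 1e6, 3.0, paper_spec, 600)


@pytest.fixture(scope="session")
def plan_3p6nm(paper_spec):
    return plan_montage(1e6, 1e6, 3.6, paper_spec, 600)


@pytest.fixture(scope="session")
def small_spec():
    """A miniature supertile for simulation tests (256-px tiles)."""
    return make_supertile_spec(256, 3, 3, 0.15)


@pytest.fixture(scope="session")
def small_scene():
    from bdtem.simulate import make_specimen

    spec = make_supertile_spec(256, 3, 3, 0.15)
    side = spec.extent_cols_px + 64
    return make_specimen(side, side, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
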