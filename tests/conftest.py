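"""Shared fixtures: small synthetic tissues reused across test modules."""

import warnings

import pytest

from adiponiche.synthetic import TissueConfig, generate_tissue

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def lean_tissue():
    return generate_tissue(TissueConfig(condition="lean", seed=11))


@pytest.fixture(scope="session")
def obese_tissue():
    return generate_tissue(TissueConfig(condition="obese", seed=11))


@pytest.fixture(scope="session")
def small_tissue():
    """A fast, small section for geometry and I/O tests."""
    cfg = TissueConfig(
        condition="obese", field_size=(800.0, 1000.0), n_cells=120, seed=7,
        niche_layout=None,
    )
    # default layout spans the configured height automatically
    return generate_tissue(cfg)
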