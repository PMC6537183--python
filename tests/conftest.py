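"""Shared fixtures: small synthetic sections generated once per session."""

import numpy as np
import pytest

import musclemorph as mm


@pytest.fixture(scope="session")
def clean_section():
    """A clean 60-fiber section: (c1, c2, truth)."""
    params = mm.SyntheticParams(n_fibers=60, seed=11)
    return mm.generate_section(params)


@pytest.fixture(scope="session")
def clean_result(clean_section):
    c1, c2, truth = clean_section
    return mm.analyze_images(c1, c2, sample_id="clean60")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
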