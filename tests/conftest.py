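"""Shared fixtures: expensive sequences are built once per session."""

import numpy as np
import pytest

from fstmd import ModelConfig, cluttered_bundle, fstmd_solve


@pytest.fixture(scope="session")
def default_config():
    return ModelConfig()


@pytest.fixture(scope="session")
def small_cluttered():
    """A reduced cluttered scene for feedback/convergence tests."""
    return cluttered_bundle(seed=7, view=(64, 64), n_frames=260)


@pytest.fixture(scope="session")
def standard_cluttered():
    """The standard 100x100 x 300-frame cluttered fixture."""
    return cluttered_bundle(seed=1)


@pytest.fixture(scope="session")
def standard_solutions(standard_cluttered):
    """Open- and closed-loop solutions on the standard fixture."""
    cfg = ModelConfig()
    out_fb, diag_fb = fstmd_solve(standard_cluttered.seq, cfg)
    out_open, diag_open = fstmd_solve(
        standard_cluttered.seq, cfg.with_(feedback_constant=0.0)
    )
    return {
        "bundle": standard_cluttered,
        "config": cfg,
        "feedback": (out_fb, diag_fb),
        "open": (out_open, diag_open),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)
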