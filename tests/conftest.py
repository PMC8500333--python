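"""Shared fixtures: small synthetic movies and their kymographs.

Expensive artefacts (full noisy movie, kymographs) are session-scoped so
the suite builds each of them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from midzone.kymograph import build_cell_kymographs
from midzone.simulate import SpindleSimConfig, generate_spindle_movie


def noiseless_config(**overrides) -> SpindleSimConfig:
    """Default movie config with noise, background and bleaching disabled."""
    base = dict(noise_model="none", noise_sd=0.0, background=0.0,
                bleach_rate_per_s=0.0, seed=0)
    base.update(overrides)
    return SpindleSimConfig(**base)


@pytest.fixture(scope="session")
def noiseless_movie():
    cfg = noiseless_config()
    stack, truth = generate_spindle_movie(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def noisy_movie():
    cfg = SpindleSimConfig(seed=7)
    stack, truth = generate_spindle_movie(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def noisy_kymographs(noisy_movie):
    cfg, stack, truth = noisy_movie
    kymos = build_cell_kymographs(stack, truth.centrosome_track())
    return cfg, truth, kymos


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
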