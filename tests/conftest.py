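"""Shared fixtures: expensive simulation runs are cached per session."""

from __future__ import annotations

import numpy as np
import pytest

import furrowsim as fs
from furrowsim.dynamics import run_simulation
from furrowsim.experiments import preset_config


@pytest.fixture(scope="session")
def archive_factory():
    """Memoized (preset, seed, overrides) -> RunArchive factory.

    Acceptance and behaviour tests share full-size runs through this
    cache so each configuration is simulated exactly once per session.
    """
    cache: dict = {}

    def get(preset: str, seed: int = 1, *, tensions=None):
        key = (preset, seed, tensions)
        if key not in cache:
            cfg = preset_config(preset, seed)
            if tensions is not None:
                cfg.mechanics = cfg.mechanics.with_tensions(*tensions)
            cache[key] = run_simulation(cfg)
        return cache[key]

    return get


@pytest.fixture()
def small_sheet():
    return fs.build_hex_sheet(4, 5, 1.0)


@pytest.fixture()
def std_sheet():
    return fs.build_hex_sheet(15, 24, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
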