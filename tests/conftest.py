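"""Shared fixtures for the test suite."""

from __future__ import annotations

import pytest

from synseed import simulate


@pytest.fixture(scope="session")
def seeded_plate():
    """A two-group plate (seeding-positive vs flat negative), fixed seed."""
    presets = [simulate.DEFAULT_PRESETS["AD+LB/APOE4-"],
               simulate.DEFAULT_PRESETS["control/APOE4-"]]
    plate, truth = simulate.simulate_plate(presets, replicates_per_sample=3,
                                           samples_per_group=4, rng_seed=11)
    return plate, truth
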