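"""Shared fixtures: simulated study conditions reused across test modules.

Simulation is cheap (a few hundred ms per condition), but session scoping
keeps the suite fast when many tests interrogate the same pooled dataset.
"""

import logging

import pytest

from badmotor.pipeline import run_condition

logging.getLogger("badmotor").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def low30():
    """Pooled LOW30 segmentation (>=350 events), fixed seed."""
    return run_condition("LOW30", seed=101, min_events=350)


@pytest.fixture(scope="session")
def high163():
    """Pooled HIGH163 segmentation (>=500 events), fixed seed."""
    return run_condition("HIGH163", seed=202, min_events=500)


@pytest.fixture(scope="session")
def med50():
    """Pooled MED50 segmentation (>=600 events for stable backslide
    completeness statistics), fixed seed."""
    return run_condition("MED50", seed=303, min_events=600)


@pytest.fixture(scope="session")
def nicktop():
    return run_condition("NICKTOP", seed=404, min_events=150)


@pytest.fixture(scope="session")
def nickbot():
    return run_condition("NICKBOT", seed=505, min_events=150)


@pytest.fixture(scope="session")
def ssb():
    return run_condition("SSB", seed=606, min_events=150)
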