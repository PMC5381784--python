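"""Shared fixtures.

The expensive preset simulations are session-scoped and reused across test
modules so the whole suite stays inside a few CPU-minutes.
"""

from __future__ import annotations

import numpy as np
import pytest

from cfcnmm.experiments import run_experiment

#: single-seed report length used throughout the suite (seconds)
REPORT_DURATION = 40.0
REPORT_SEED = 1


def _report(name: str):
    return run_experiment(name, seed=REPORT_SEED, duration=REPORT_DURATION,
                          transient=10.0, n_seeds=1)


@pytest.fixture(scope="session")
def report_pfc():
    return _report("PFC")


@pytest.fixture(scope="session")
def report_pac():
    return _report("PAC")


@pytest.fixture(scope="session")
def report_ffc():
    return _report("FFC")


@pytest.fixture(scope="session")
def report_aac():
    return _report("AAC")


@pytest.fixture(scope="session")
def report_afc():
    return _report("AFC")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
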