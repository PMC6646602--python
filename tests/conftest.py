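"""Shared fixtures.

The two full-size batches (2,000 sessions x 225 steps per dyad, the batch
size used throughout for across-session distributions) are expensive, so they
are computed once per test session and shared by every test that needs
across-session distributions.
"""

from __future__ import annotations

import numpy as np
import pytest

from secondsim import (
    SessionConfig,
    initiative_centered_dyad,
    play_centered_dyad,
    run_batch,
    summarize_records,
)

BATCH_SESSIONS = 2000
BATCH_SEED = 20_260_921


@pytest.fixture(scope="session")
def play_records():
    config = SessionConfig(dyad=play_centered_dyad(), seed=BATCH_SEED)
    return run_batch(config, BATCH_SESSIONS)


@pytest.fixture(scope="session")
def initiative_records():
    config = SessionConfig(dyad=initiative_centered_dyad(), seed=BATCH_SEED + 1)
    return run_batch(config, BATCH_SESSIONS)


@pytest.fixture(scope="session")
def play_rows(play_records):
    return summarize_records(play_records)


@pytest.fixture(scope="session")
def initiative_rows(initiative_records):
    return summarize_records(initiative_records)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
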