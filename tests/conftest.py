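import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from episodelog import lexicon, synthlogs
from episodelog.logio import SearchLog, StudyWindow

TEST_WINDOW = StudyWindow(dt.date(2011, 12, 1), dt.date(2012, 5, 31))


def make_log(rows, window=TEST_WINDOW) -> SearchLog:
    """Build a SearchLog from (user_id, 'YYYY-MM-DDTHH:MM', text, clicks) tuples."""
    df = pd.DataFrame(rows, columns=["user_id", "timestamp", "query_text", "clicks"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return SearchLog(df=df, window=window)


def make_annotated(rows, window=TEST_WINDOW) -> SearchLog:
    return lexicon.annotate(make_log(rows, window))


@pytest.fixture(scope="session")
def small_sim():
    """Mixed-population simulation small enough for unit tests."""
    cfg = synthlogs.GeneratorConfig(
        n_recurring=30, n_occasional=12, n_lithium_only=12, n_control=16, seed=5
    )
    return cfg, synthlogs.generate(cfg)


@pytest.fixture(scope="session")
def small_annotated(small_sim):
    _, (log, panel, truth) = small_sim
    return lexicon.annotate(log), panel, truth


# ---- heavy session fixtures shared by the acceptance tests ----

RECURRING_N = 500
ACCEPT_SEED = 1


def _recurring_config(seed=ACCEPT_SEED, n=RECURRING_N):
    return synthlogs.GeneratorConfig(
        n_recurring=n, n_occasional=0, n_lithium_only=0, n_control=0, seed=seed
    )


@pytest.fixture(scope="session")
def default_sim_annotated():
    log, panel, truth = synthlogs.generate(_recurring_config())
    return lexicon.annotate(log), panel, truth


@pytest.fixture(scope="session")
def null_sim_annotated():
    cfg = synthlogs.null_config(_recurring_config())
    log, panel, truth = synthlogs.generate(cfg)
    return lexicon.annotate(log), panel, truth
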