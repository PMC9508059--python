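import numpy as np
import pandas as pd
import pytest

import slonline as sl


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def exp1a_run_frame():
    rng = np.random.default_rng(7)
    chunks = sl.make_chunks(sl.EXP1A, rng)
    return sl.trials_to_frame(sl.generate_run(sl.EXP1A, chunks, rng)), chunks


@pytest.fixture(scope="session")
def exp2_run_frame():
    rng = np.random.default_rng(8)
    chunks = sl.make_chunks(sl.EXP2, rng)
    return sl.trials_to_frame(sl.generate_run(sl.EXP2, chunks, rng)), chunks


@pytest.fixture(scope="session")
def primed_exp2_cohort():
    """Small warm-up-design cohort with the default (priming) observer."""
    return sl.make_cohort(sl.EXP2, 6, sl.ObserverParams(), seed=42)


@pytest.fixture(scope="session")
def preprocessed_exp2(primed_exp2_cohort):
    table, report = sl.preprocess(
        primed_exp2_cohort, sl.FilterConfig(sd_multiplier=2.0)
    )
    return table, report
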