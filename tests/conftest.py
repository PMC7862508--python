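import numpy as np
import pandas as pd
import pytest

from gscore import SummaryStats, simulate


def make_sumstats(trait="trait", cohort=None, **cols) -> SummaryStats:
    """Hand-build a SummaryStats from parallel column lists."""
    return SummaryStats(trait=trait, df=pd.DataFrame(cols), cohort=cohort)


@pytest.fixture(scope="session")
def tiny_output():
    """10 SNPs x 60 samples plus matched summary statistics (seeded)."""
    return simulate.make_fixture("tiny")


@pytest.fixture(scope="session")
def mr_tables():
    """242-instrument analytic two-sample tables, no pleiotropy, seeded."""
    cfg = simulate.SimConfig(seed=1234)
    return simulate.simulate_summary_stats(cfg, include_second_exposure=True)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
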