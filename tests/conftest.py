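import numpy as np
import pytest

from itsar import MonthIndex, SimulationConfig, StudyDesign, simulate_series

JULY_2011 = MonthIndex(2011, 7)


@pytest.fixture
def study_design():
    """The canonical advisory window: 24 pre months, 11 post months,
    July 2011 transitional, monthly seasonal dummies."""
    return StudyDesign(advisory_month=JULY_2011)


@pytest.fixture
def plain_design():
    """Same window without seasonal dummies (4-column design)."""
    return StudyDesign(advisory_month=JULY_2011, seasonal=False)


def noiseless_series(beta, seasonal=0.0, n_pre=24, n_post=11,
                     start=MonthIndex(2009, 7), post_trend_start=1):
    """A deterministic series lying exactly on the segmented model."""
    cfg = SimulationConfig(
        beta=beta, seasonal=seasonal, phi=(), innovation_sd=0.0,
        n_pre=n_pre, n_post=n_post, start_month=start,
        post_trend_start=post_trend_start,
    )
    series, truth = simulate_series(cfg, seed=0)
    return series, truth, cfg


@pytest.fixture
def noisy_series():
    series, truth = simulate_series(SimulationConfig(), seed=42)
    return series, truth


def ar1_noise(rng, n, phi, sd=1.0, burn=200):
    e = np.empty(n + burn)
    prev = 0.0
    for t, z in enumerate(rng.normal(0.0, sd, n + burn)):
        prev = phi * prev + z
        e[t] = prev
    return e[burn:]
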