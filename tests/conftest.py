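import warnings

import matplotlib

matplotlib.use("Agg")

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

import numpy as np
import pytest

import detphot as dp

#: reduced sampler settings for unit tests (convergence thresholds are only
#: asserted where a test is specifically about convergence)
FAST = dict(chains=2, iterations=1500, thin=2)


@pytest.fixture(scope="session")
def paper_design() -> dp.ExperimentDesign:
    """The real study layout: 4 treatments × 4 tanks × 7 bags, 6 days."""
    return dp.ExperimentDesign()


@pytest.fixture(scope="session")
def synthetic_experiment(paper_design):
    """One full synthetic experiment at the default (published-regime) truth."""
    truth = dp.TruthParams(seed=11)
    registry, series = dp.simulate_experiment(paper_design, truth)
    return truth, registry, series


@pytest.fixture(scope="session")
def rate_records(synthetic_experiment):
    _, registry, series = synthetic_experiment
    return dp.process_experiment(registry, series)


@pytest.fixture(scope="session")
def rate_fit(rate_records):
    """A shared stage-2 fit on the session's synthetic experiment."""
    model = dp.RateDeclineModel(rate_records, response="net")
    return model, model.fit(dp.SamplerConfig(seed=5, **FAST))


@pytest.fixture(scope="session")
def viability_fit(rate_records):
    model = dp.ViabilityModel.from_rate_records(rate_records, "autotrophy")
    return model, model.fit(dp.SamplerConfig(seed=5, **FAST))


def make_series(slope_per_min, n=30, noise_sd=0.0, o2_start=220.0, seed=0,
                phase="light", **kwargs):
    """Linear O₂ series helper used across respirometry tests."""
    rng = np.random.default_rng(seed)
    times = np.arange(n) * 10.0
    o2 = o2_start + slope_per_min * times / 60.0
    if noise_sd > 0:
        o2 = o2 + rng.normal(0, noise_sd, n)
    return dp.IncubationSeries(sample_id="t", phase=phase, times=times, o2=o2,
                               **kwargs)
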