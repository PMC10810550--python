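import numpy as np
import pytest

from firefreq import models as m
from firefreq import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_specs():
    return syn.TruncNormalSpec(), syn.RainfallModelSpec(), syn.CountModelSpec()


@pytest.fixture
def small_series():
    """One deterministic theta=1.5, n=60 replicate under the default specs."""
    scen = syn.ScenarioConfig(n=60, theta=1.5, n_replicates=5, master_seed=76568)
    return syn.generate_series(scen, replicate_id=0)


@pytest.fixture
def short_sampler():
    """Short-chain MCMC settings used to keep tests fast."""
    return m.SamplerSettings(n_walkers=12, n_warmup=300, n_keep=150)


def nb_sample_series(coef, theta, n, seed):
    """Series whose counts are genuine NB draws at known coefficients."""
    scen = syn.ScenarioConfig(n=n, theta=theta, n_replicates=1, master_seed=seed)
    count = syn.CountModelSpec(coef=coef, theta=theta, mode="nb_sample")
    return syn.generate_series(scen, count=count, replicate_id=0)
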