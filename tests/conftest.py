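import pytest
from hypothesis import HealthCheck, settings

import rotabayes as rb

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_records():
    """Seeded ~200-record synthetic record set with its ground truth."""
    return rb.generate(rb.small_fixture_config())


@pytest.fixture(scope="session")
def dense_records():
    """Larger seeded record set in which every non-cotton crop is
    expected to survive into the model-1/2 designs."""
    import dataclasses

    cfg = dataclasses.replace(
        rb.small_fixture_config(),
        n_fields=90,
        n_records=420,
        p_yield_missing=0.05,
        p_adj_missing=0.05,
        master_seed=7_031_644,
    )
    return rb.generate(cfg)


@pytest.fixture(scope="session")
def fast_mcmc():
    return rb.McmcConfig(n_chains=3, n_iter=1500, n_burn=500, master_seed=42)


@pytest.fixture(scope="session")
def fitted_model1(fixture_records, fast_mcmc):
    """One shared model-1 fit on the small fixture."""
    records, _ = fixture_records
    cfg = rb.PipelineConfig(mcmc=fast_mcmc)
    return rb.run_model(1, records, cfg)
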