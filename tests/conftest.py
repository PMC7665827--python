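import pytest

from neocea import (
    AnalysisConfig,
    Demography,
    SocialValueChoice,
    baseline_rates_from,
    run_psa,
)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig.default()


@pytest.fixture(scope="session")
def reference_registry(config):
    """The packaged 2012-2016 delivery registry."""
    return config.load_registry()


@pytest.fixture(scope="session")
def reference_ledger(config):
    return config.load_ledger()


@pytest.fixture(scope="session")
def rates(reference_registry):
    return baseline_rates_from(reference_registry, 2012)


@pytest.fixture(scope="session")
def demo():
    return Demography()


@pytest.fixture(scope="session")
def svc_discounted():
    return SocialValueChoice.discounted_age_weighted()


@pytest.fixture(scope="session")
def psa_sample(reference_registry, reference_ledger, config):
    """One shared 10,000-draw PSA run under the default SE convention."""
    return run_psa(reference_registry, reference_ledger,
                   n_draws=config.n_draws, seed=config.seed,
                   se_convention="sample")


@pytest.fixture(scope="session")
def psa_poisson(reference_registry, reference_ledger, config):
    """The same run under the per-count Poisson SE convention."""
    return run_psa(reference_registry, reference_ledger,
                   n_draws=config.n_draws, seed=config.seed,
                   se_convention="poisson")
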