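import numpy as np
import pytest

from readrel.corpus import CorpusConfig, EffectSpec, simulate_responses
from readrel.model import ModelSpec, SamplerConfig, build_design, fit


def single_predictor_specs(
    rho_wl: float = 0.75, sd_wl: float = 0.05, beta_wl: float = 0.05
):
    """Effect specs with only intercept and word-length variability."""
    return (
        EffectSpec("intercept", 0.0, 0.2, 0.2, 0.7),
        EffectSpec("wl", beta_wl, sd_wl, sd_wl, rho_wl),
        EffectSpec("freq", -0.04, 0.0, 0.0, 0.0),
        EffectSpec("surp", 0.03, 0.0, 0.0, 0.0),
        EffectSpec("depdist", 0.0, 0.0, 0.0, 0.0),
        EffectSpec("nleftdep", 0.0, 0.0, 0.0, 0.0),
    )


@pytest.fixture(scope="session")
def small_lognormal_fit():
    """One small but well-posed two-session fit, shared across tests."""
    cfg = CorpusConfig(
        n_subjects=20,
        words_per_session=(150, 150),
        effect_specs=single_predictor_specs(),
        seed=101,
    )
    trials, truth = simulate_responses(cfg)
    spec = ModelSpec(family="lognormal", predictors=("wl",))
    bundle = build_design(trials, spec)
    posterior = fit(
        bundle,
        spec,
        SamplerConfig(chains=2, iterations=600, warmup=300, seed=7),
        n_subject_draws=50,
    )
    return posterior, truth, bundle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
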