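import numpy as np
import pytest

from lsirt import (DGPConfig, ItemResponseData, ModelSpec, ParameterState,
                   PosteriorDraws, PriorConfig, generate_parameters,
                   generate_responses)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_state(rng, P=6, I=4, D=2, K=2, gamma=0.8, mix_w=None):
    """A random valid ParameterState (positive a, PD correlation)."""
    corr = np.eye(D)
    if D > 1:
        rho = rng.uniform(-0.3, 0.5)
        corr = np.full((D, D), rho)
        np.fill_diagonal(corr, 1.0)
    return ParameterState(
        theta=rng.standard_normal((P, D)),
        a=np.exp(rng.normal(0, 0.3, I)),
        beta=rng.normal(0, 1, I),
        Z=rng.standard_normal((P, K)),
        W=rng.standard_normal((I, K)),
        gamma=gamma,
        theta_corr=corr,
        mix_w=mix_w,
    )


def random_data(rng, P=6, I=4, D=2):
    resp = (rng.random((P, I)) < 0.5).astype(float)
    # ensure nothing degenerate
    resp[0] = 1.0 - resp[1]
    item_factor = 1 + (np.arange(I) % D)
    return ItemResponseData(responses=resp, item_factor=item_factor)


def make_draws(params, log_post, spec, data, seed=0, aligned=False):
    return PosteriorDraws(params=params, log_post=np.asarray(log_post, float),
                          spec=spec, data=data, seed=seed, aligned=aligned)


@pytest.fixture
def small_dataset(rng):
    """(truth, data, spec) at desk-miniature scale with real CD."""
    cfg = DGPConfig(P=40, D=2, I_per_factor=3, seed=7)
    truth = generate_parameters(cfg)
    spec = ModelSpec.mls2plm(2, prior=PriorConfig(gamma_prior_mode="slab_spike"))
    data = generate_responses(truth, ModelSpec.mls2plm(2), cfg.item_factor, seed=8)
    return truth, data, spec
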