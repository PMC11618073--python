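import pytest

import flipkin as fk


@pytest.fixture(scope="session")
def small_flipping_ensemble():
    """25 canonical flipping traces; enough for gate/idealizer checks."""
    params = fk.FlippingParams()
    traces, manifest = fk.simulate_flipping_ensemble(
        params, "canonical", n_traces=25, duration=200.0, seed=42
    )
    return params, traces, manifest


@pytest.fixture(scope="session")
def small_exchange_ensemble():
    """40 three-colour exchange traces with ground truth."""
    params = fk.ExchangeParams()
    traces, manifest = fk.simulate_exchange_ensemble(
        params, n_traces=40, duration=1200.0, seed=42
    )
    return params, traces, manifest


@pytest.fixture()
def noiseless_optics():
    return fk.OpticsConfig(
        noise_sd=0.0,
        bleedthrough_beta=0.0,
        background=0.0,
        bleach_rate_donor=0.0,
        bleach_rate_acceptor=0.0,
        bleach_rate_red=0.0,
    )
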