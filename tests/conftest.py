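import warnings

import pytest

import nitrokin as nk


@pytest.fixture(scope="session")
def truth():
    return nk.GroundTruth()


@pytest.fixture(scope="session")
def nitronium_model(truth):
    """Two-stage model fitted to a noise-free synthetic table with the
    exact affine structure, so it evaluates the truth surface exactly."""
    return nk.fit_nitronium(nk.generate_nitronium_table(truth.nitronium))


@pytest.fixture(scope="session")
def noisefree_campaign(truth):
    return nk.generate_campaign(truth, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def fitted_params(noisefree_campaign, nitronium_model):
    table = nk.fit_rate_table(noisefree_campaign.series)
    return nk.IntrinsicParams.fit(table, nitronium_model)


@pytest.fixture(autouse=True)
def _no_mc_range_warnings():
    """Silence the Mc out-of-calibration warnings that extrapolation
    tests deliberately trigger."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mc evaluated at")
        yield
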