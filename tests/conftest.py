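import dataclasses

import pytest

from znbind.scenario import scenario_paper_mimic


@pytest.fixture(scope="session")
def truth():
    """The default 13-point Zn titration scenario."""
    return scenario_paper_mimic()


@pytest.fixture(scope="session")
def noiseless_truth(truth):
    """Same scenario with every noise source switched off."""
    return dataclasses.replace(truth, spectrum_noise_sd=0.0,
                               tht_noise_sd=0.0, atd_noise_sd=0.0,
                               csp_noise_sd=0.0)
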