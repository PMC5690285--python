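import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
_hyp_settings.load_profile("deterministic")

from ptmstoich import (  # noqa: E402
    SilacSimConfig,
    TMTSimConfig,
    simulate_heavy_only_reference,
    simulate_silac_pair,
    simulate_tmt,
)


@pytest.fixture(scope="session")
def silac_sim():
    """Default simulated SILAC pair: (table, truth, reference ratios)."""
    config = SilacSimConfig(seed=0)
    table, truth = simulate_silac_pair(config)
    reference = simulate_heavy_only_reference(
        config.e_true, config.n_reference_psms, config.noise_sigma, seed=10_000
    )
    return table, truth, reference


@pytest.fixture(scope="session")
def tmt_sim():
    """Default simulated TMT experiment: (table, truth)."""
    table, truth = simulate_tmt(TMTSimConfig(seed=0))
    return table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
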