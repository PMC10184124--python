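import numpy as np
import pytest

import lipidspring as ls

# Reference spring parameters of the two glycolipid anchors (Le^X and Lac2
# lipids at 303 K), used as generator ground truth throughout the suite.
LEX_UNBIASED = dict(k=94.0, z0=-0.31)
LEX_PULLING = dict(k=86.0, z0=-0.34)
LAC2_UNBIASED = dict(k=109.0, z0=-0.31)
TEMPERATURE_K = 303.0


@pytest.fixture(scope="session")
def lex_pool():
    """Ten force-free replicas of the stiffer-anchor sensor (k = 94 pN/nm),
    2000 ns each: enough frames for stable Boltzmann inversion in tests."""
    return [
        ls.simulate_ou(
            ls.default_params(seed=100 + i, temperature=TEMPERATURE_K, **LEX_UNBIASED), 2000.0
        )
        for i in range(10)
    ]


@pytest.fixture(scope="session")
def lex_boltzmann_cal(lex_pool):
    return ls.boltzmann_calibrate(lex_pool, temperature=TEMPERATURE_K)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
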