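import numpy as np
import pytest

from quarg import synthetic


@pytest.fixture(scope="session")
def strong_cohort():
    """Strongly-signaled cohort: 12 candidate features, 4 planted, effect 2."""
    cfg = synthetic.SyntheticConfig(
        n_patients=400,
        n_img_features=6,
        n_gen_features=6,
        n_informative_img=2,
        n_informative_gen=2,
        n_redundant=2,
        effect_size=2.0,
        site_count=3,
        site_shift_sd=0.3,
        missing_rate=0.0,
        seed=11,
    )
    return synthetic.generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
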