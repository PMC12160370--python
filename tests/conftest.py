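import numpy as np
import pytest

from tonguedx.constitutions import Constitution
from tonguedx.synthetic import DEFAULT_PHENOTYPES, generate_sample


@pytest.fixture(scope="session")
def cohort100():
    """100 balanced 64x64 synthetic samples (20 per constitution)."""
    phens = list(DEFAULT_PHENOTYPES.values())
    samples = []
    for i in range(100):
        s = generate_sample(phens[i % 5], (64, 64), 100 + i)
        s.sample_id = f"s{i:03d}"
        samples.append(s)
    return samples


@pytest.fixture(scope="session")
def backbone100(cohort100):
    """Tiny residual backbone trained on the shared cohort (seed 0)."""
    from tonguedx.features_deep import TINY_BACKBONE_PRESET, train_backbone

    model, history = train_backbone(cohort100, TINY_BACKBONE_PRESET(seed=0, epochs=30))
    return model, history


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def all_constitutions():
    return list(Constitution)
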