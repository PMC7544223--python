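import numpy as np
import pytest

from bitome import core, synth


@pytest.fixture(scope="session")
def synth_data():
    """One medium synthetic genome shared across the suite."""
    config = synth.SyntheticConfig(seed=7)
    sequence, features, truth = synth.generate_annotation(config)
    return sequence, features, truth


@pytest.fixture(scope="session")
def built(synth_data):
    sequence, features, _ = synth_data
    return core.build(sequence, features, core.BuildConfig())


@pytest.fixture(scope="session")
def nucleobase_only():
    rng = np.random.default_rng(11)
    sequence = "".join(rng.choice(list("ACGT"), size=400))
    return core.build(sequence, [], core.BuildConfig())
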