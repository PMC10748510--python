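import numpy as np
import pytest

from contourclf.features import default_registry
from contourclf.synthetic import (
    GeneratorConfig,
    generate_auxiliary,
    generate_corpus,
    generate_lexicons,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def gen_cfg():
    return GeneratorConfig(
        n_docs=60, effect_size=1.5, p_case=0.5, p_control=0.05,
        r_emotion=(0.5, 0.0, 0.0, 0.0, 0.0, 0.0),
        r_personality=(0.4, 0.0, 0.0, 0.0), seed=7,
    )


@pytest.fixture(scope="session")
def lexicons(gen_cfg):
    return generate_lexicons(gen_cfg)


@pytest.fixture(scope="session")
def small_docs(gen_cfg, lexicons):
    docs = generate_corpus(gen_cfg, lexicons)
    return generate_auxiliary(gen_cfg, docs)


@pytest.fixture(scope="session")
def planted_contour_data():
    """Synthetic contour arrays where only the first 5 columns carry
    class signal; everything else is standard normal noise."""
    rng = np.random.default_rng(11)
    n, W, F = 240, 6, 40
    inputs, labels = [], []
    for i in range(n):
        y = i % 2
        x = rng.normal(size=(W, F))
        if y:
            x[:, :5] += 1.5
        inputs.append(x)
        labels.append(y)
    return inputs, np.array(labels)
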