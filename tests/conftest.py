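import numpy as np
import pytest

from reappear.simulate import SyntheticConfig, draw_story_metrics, paper_shaped_corpus


@pytest.fixture(scope="session")
def paper_corpus():
    """123-story direct-mode corpus with the 92/9/22 rating split."""
    return paper_shaped_corpus(seed=11)


@pytest.fixture(scope="session")
def balanced_corpus():
    """Balanced 100-per-level corpus with the default study-shaped effects."""
    cfg = SyntheticConfig(counts_per_rating={r: 100 for r in (-2, -1, 0, 1, 2)},
                          mode="direct", seed=17)
    return draw_story_metrics(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
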