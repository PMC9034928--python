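import numpy as np
import pytest

from drugner.config import RunConfig
from drugner.synthetic import build_lexicon, generate_corpus, separable_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """60 separable sentences: enough structure for alphabet/encoding tests."""
    return generate_corpus(separable_spec(n_sentences=60, seed=7))


@pytest.fixture(scope="session")
def small_lexicon():
    return build_lexicon(n_norm_ids=12, synonymy=2, seed=3)


@pytest.fixture
def tiny_config():
    """A desk-scale model configuration for fast unit tests."""
    return RunConfig(
        task="multitask",
        feedback=True,
        state_size=8,
        word_dim=8,
        char_dim=5,
        num_filters=6,
        elmo_dim=8,
        channels=("word", "char"),
        epochs=1,
        seed=0,
    )


def random_spans(rng, n_tokens, types=("DRUG", "BRAND"), max_spans=3):
    """Non-overlapping random token spans (an independent construction)."""
    spans = []
    free = list(range(n_tokens))
    for _ in range(int(rng.integers(0, max_spans + 1))):
        if not free:
            break
        start = int(rng.choice(free))
        length = int(rng.integers(1, 3))
        end = min(start + length - 1, n_tokens - 1)
        if all(not (s <= end and start <= e) for s, e, _ in spans):
            spans.append((start, end, str(rng.choice(types))))
    return sorted(spans)
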