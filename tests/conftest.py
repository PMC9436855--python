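import numpy as np
import pytest

from litmet.embeddings import EmbeddingLexicon

# 10-word, 4-dim hand-set fixture used across modules
VOCAB10 = {
    "ant": [1.0, 0.2, 0.0, 0.1],
    "bee": [0.9, 0.3, 0.1, 0.0],
    "cat": [0.2, 1.0, 0.1, 0.0],
    "dog": [0.1, 0.9, 0.2, 0.1],
    "eel": [0.0, 0.1, 1.0, 0.3],
    "fox": [0.1, 0.0, 0.9, 0.4],
    "gnu": [0.3, 0.1, 0.2, 1.0],
    "hen": [0.2, 0.2, 0.3, 0.9],
    "ibis": [0.5, 0.5, 0.1, 0.2],
    "jay": [0.4, 0.1, 0.5, 0.5],
}


def make_lexicon(vocab: dict) -> EmbeddingLexicon:
    return EmbeddingLexicon(
        tuple(vocab), np.array(list(vocab.values()), dtype=float)
    ).normalized()


def random_lexicon(rng: np.random.Generator, n_words: int, d: int) -> dict:
    """Random raw vocabulary dict (word -> list of floats), no zero vectors."""
    vocab = {}
    for i in range(n_words):
        v = rng.normal(size=d)
        while np.linalg.norm(v) < 1e-6:
            v = rng.normal(size=d)
        vocab[f"w{i:04d}"] = v.tolist()
    return vocab


@pytest.fixture
def lex10() -> EmbeddingLexicon:
    return make_lexicon(VOCAB10)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
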