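import numpy as np
import pytest

from speechtrf.features import build_impulse_series, build_onset_regressor
from speechtrf.ngram import train_kneser_ney
from speechtrf.synthetic import LexiconSpec, TranscriptSpec, generate_corpus, generate_embeddings, generate_transcript
from speechtrf.tokens import WordToken


@pytest.fixture(scope="session")
def embeddings():
    return generate_embeddings(
        LexiconSpec(vocab_size=100, embed_dim=16, n_categories=5,
                    within_category_similarity=0.7, seed=11)
    )


@pytest.fixture(scope="session")
def corpus(embeddings):
    return generate_corpus(embeddings, n_sentences=300, transition_temperature=0.5,
                           seed=7)


@pytest.fixture(scope="session")
def ngram_model(corpus):
    with np.errstate(all="ignore"):
        return train_kneser_ney(corpus, order=5)


@pytest.fixture(scope="session")
def transcript(corpus):
    spec = TranscriptSpec(duration_s=120.0, seed=3)
    return generate_transcript(spec, corpus)


def make_tokens(words, spacing=0.5, sentence_len=None, is_content=True):
    """Evenly spaced helper tokens; sentence_len splits into sentences."""
    toks = []
    for i, w in enumerate(words):
        sid = 0 if sentence_len is None else i // sentence_len
        toks.append(
            WordToken(word=w, onset_s=i * spacing, offset_s=i * spacing + 0.3,
                      sentence_id=sid, is_content=is_content)
        )
    return toks


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
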