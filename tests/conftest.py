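import numpy as np
import pytest

from topicrisk import embedding, synthetic
from topicrisk.preprocess import Comment, Vocabulary


def make_vocab(words, counts=None):
    words = list(words)
    counts = counts or {w: 1 for w in words}
    return Vocabulary(index={w: i for i, w in enumerate(words)},
                      counts=counts,
                      total_token_count=sum(counts.values()))


def make_model(vectors: dict[str, list[float]], topic_ids=("t0", "t1")):
    """Embedding model with hand-set input vectors (outputs zero)."""
    words = list(vectors)
    vocab = make_vocab(words)
    d = len(next(iter(vectors.values())))
    cfg = embedding.TrainingConfig(dimension=d)
    m = embedding.EmbeddingModel.initialize(vocab, cfg, list(topic_ids))
    m.w_in = np.array([vectors[w] for w in words], dtype=float)
    return m


def comment(tokens, cid="c0", label=-1):
    return Comment(comment_id=cid, raw_text=" ".join(tokens),
                   tokens=list(tokens), label=label)


@pytest.fixture(scope="session")
def small_corpus():
    """50 short comments over a 60-word vocabulary, planted 2-topic."""
    cfg = synthetic.GeneratorConfig(
        n_comments=50, background_vocab_size=40, words_per_topic=10,
        min_length=4, max_length=8, ultrashort_fraction=0.0, rng_seed=101)
    return synthetic.generate_corpus(cfg)


@pytest.fixture(scope="session")
def trained_small(small_corpus):
    comments, truth, tdict = small_corpus
    cfg = embedding.TrainingConfig(dimension=12, epochs=3, window=3,
                                   rng_seed=101)
    return embedding.train(comments, tdict, cfg)
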