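import numpy as np
import pytest

from plebeian import SyntheticConfig, generate_corpus, score_corpus
from plebeian.corpus import Corpus, Post, Thread


@pytest.fixture
def tiny_thread():
    root = Post(post_id="r1", text="good day", views=500)
    comments = [
        Post(post_id=f"c{i}", text=text, parent_id="r1")
        for i, text in enumerate(
            ["bad news", "terrible scam", "great work", "awful hoax", "nice find"]
        )
    ]
    return Thread(root=root, comments=comments)


@pytest.fixture
def tiny_corpus(tiny_thread):
    return Corpus(threads=[tiny_thread])


@pytest.fixture(scope="session")
def demo_corpus():
    """Mid-size synthetic corpus shared across read-only tests."""
    corpus, truth = generate_corpus(SyntheticConfig(n_threads=400, seed=42))
    return corpus, truth


@pytest.fixture(scope="session")
def demo_scores(demo_corpus):
    corpus, _ = demo_corpus
    return dict(score_corpus(corpus))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
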