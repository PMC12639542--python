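import pytest

from matkg.corpus import AnnotatedParagraph, tokens_from_strings
from matkg.encoders import HashEncoder
from matkg.synth import GeneratorConfig, generate


def make_paragraph(pid, sentences, tags):
    """Build a paragraph from per-sentence word lists and tag lists."""
    words, all_tags, bounds = [], [], []
    for sent_words, sent_tags in zip(sentences, tags):
        start = len(words)
        words.extend(sent_words)
        all_tags.extend(sent_tags)
        bounds.append((start, len(words)))
    return AnnotatedParagraph(
        paragraph_id=pid, tokens=tokens_from_strings(words),
        tags=all_tags, sentences=bounds,
    )


@pytest.fixture(scope="session")
def encoder():
    return HashEncoder(d=16, seed=0)


@pytest.fixture(scope="session")
def small_corpus():
    """A deterministic 30-paragraph gold corpus shared across tests."""
    return generate(GeneratorConfig(n_paragraphs=30, seed=5))


@pytest.fixture
def simple_paragraph():
    return make_paragraph(
        "p0",
        [["Bioactive", "glass", "was", "prepared", "with", "TEP", "."],
         ["It", "was", "stirred", "at", "100", "°C", "."]],
        [["BE", "EE", "O", "O", "O", "BC", "O"],
         ["O", "O", "BM", "O", "BD", "ED", "O"]],
    )
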