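"""Annotation data model, BIOE tag codec, corpus I/O and the train/validation split.

The unit of processing is the :class:`AnnotatedParagraph`: a tokenized
paragraph with sentence boundaries, one tag per token, and the entity
mentions derivable from those tags.  Tags are either ``"O"`` or a
two-letter code ``<position><category>`` where position is ``B`` (begin),
``I`` (inside) or ``E`` (end) and category is one of the six entity
classes used for materials-synthesis text:

====  =========================================
 E    material entity ("bioactive glass", "BG")
 C    experimental condition or reagent ("TEP", "citric acid")
 D    value in the experimental phase ("100 °C", "24 h")
 M    experimental step ("stirred", "calcined")
 R    material property category ("SSA", "pore size")
 V    material property value ("350 m2/g")
====  =========================================

A span is written ``B`` alone (singleton), or ``B`` + ``I``* + ``E``.
All offsets are 0-based and half-open.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field

CATEGORIES = ("E", "C", "D", "M", "R", "V")

_TAG_RE = re.compile(r"^(O|[BIE][ECDMRV])$")


class SchemaError(ValueError):
    """A tag string or annotation structure violates the schema."""


class DecodingError(ValueError):
    """Tag sequence cannot be decoded into spans under strict rules."""


class ParseError(ValueError):
    """Corpus file is malformed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class Token:
    """One surface token with its character extent in the paragraph text."""

    text: str
    char_start: int
    char_end: int

    def __post_init__(self):
        if not (0 <= self.char_start < self.char_end):
            raise SchemaError(
                f"invalid token extent [{self.char_start}, {self.char_end})"
            )


@dataclass(frozen=True)
class EntityMention:
    """A decoded contiguous span: category plus token extent (half-open)."""

    category: str
    token_start: int
    token_end: int
    paragraph_id: str = ""
    mention_id: str = ""
    surface: str = ""

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise SchemaError(f"unknown category {self.category!r}")
        if not (0 <= self.token_start < self.token_end):
            raise SchemaError(
                f"invalid mention extent [{self.token_start}, {self.token_end})"
            )

    @property
    def span(self) -> tuple[int, int]:
        return (self.token_start, self.token_end)


@dataclass
class AnnotatedParagraph:
    """A tokenized, tagged paragraph with sentence boundaries.

    ``sentences`` is a list of half-open token-index intervals that
    partitions ``range(len(tokens))``.  ``mentions`` caches the decoded
    entity mentions; it is filled lazily by :meth:`get_mentions`.
    """

    paragraph_id: str
    tokens: list[Token]
    tags: list[str]
    sentences: list[tuple[int, int]]
    _mentions: list[EntityMention] | None = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.tokens) != len(self.tags):
            raise SchemaError(
                f"paragraph {self.paragraph_id}: {len(self.tokens)} tokens "
                f"but {len(self.tags)} tags"
            )
        validate_tags(self.tags)
        cursor = 0
        for start, end in self.sentences:
            if start != cursor or end <= start:
                raise SchemaError(
                    f"paragraph {self.paragraph_id}: sentence intervals "
                    f"must partition the token range"
                )
            cursor = end
        if self.sentences and cursor != len(self.tokens):
            raise SchemaError(
                f"paragraph {self.paragraph_id}: sentences cover {cursor} "
                f"of {len(self.tokens)} tokens"
            )

    @property
    def text(self) -> str:
        out = []
        pos = 0
        for tok in self.tokens:
            out.append(" " * (tok.char_start - pos))
            out.append(tok.text)
            pos = tok.char_end
        return "".join(out)

    def sentence_of(self, token_index: int) -> int:
        for i, (start, end) in enumerate(self.sentences):
            if start <= token_index < end:
                return i
        raise IndexError(f"token index {token_index} outside all sentences")

    def get_mentions(self, strict: bool = True) -> list[EntityMention]:
        if self._mentions is None:
            self._mentions = decode_tags(self, strict=strict)
        return self._mentions

    def surface_of(self, span: tuple[int, int]) -> str:
        return " ".join(t.text for t in self.tokens[span[0] : span[1]])

    def to_json(self) -> dict:
        return {
            "paragraph_id": self.paragraph_id,
            "tokens": [[t.text, t.char_start, t.char_end] for t in self.tokens],
            "tags": list(self.tags),
            "sentences": [list(s) for s in self.sentences],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "AnnotatedParagraph":
        return cls(
            paragraph_id=obj["paragraph_id"],
            tokens=[Token(t, s, e) for t, s, e in obj["tokens"]],
            tags=list(obj["tags"]),
            sentences=[tuple(s) for s in obj["sentences"]],
        )


@dataclass(frozen=True)
class CorpusSplit:
    """Paragraph-level train/validation partition."""

    train: tuple[str, ...]
    validation: tuple[str, ...]
    seed: int
    ratio: tuple[int, int]


def validate_tags(tags: list[str]) -> None:
    """Raise :class:`SchemaError` naming the first syntactically bad tag."""
    for i, tag in enumerate(tags):
        if not _TAG_RE.match(tag):
            raise SchemaError(f"malformed tag {tag!r} at index {i}")


def tokens_from_strings(words: list[str]) -> list[Token]:
    """Build :class:`Token` objects with offsets from space-joined words."""
    tokens = []
    pos = 0
    for w in words:
        tokens.append(Token(w, pos, pos + len(w)))
        pos += len(w) + 1
    return tokens


def decode_tags(
    paragraph: AnnotatedParagraph, strict: bool = True
) -> list[EntityMention]:
    """Decode the tag sequence into maximal contiguous entity spans.

    A span opens at ``B<cat>``, extends through ``I<cat>`` of the same
    category, and closes at ``E<cat>`` or at the next tag that does not
    continue it.  A lone ``B<cat>`` token is a complete singleton mention.

    In strict mode an ``I``/``E`` tag with no open span of its category
    raises :class:`DecodingError`; in lenient mode (for model output) the
    orphan tag is salvaged as the start of a new span.
    """
    tags = paragraph.tags
    validate_tags(tags)
    mentions: list[EntityMention] = []
    open_cat: str | None = None
    open_start = 0

    def close(end: int) -> None:
        nonlocal open_cat
        if open_cat is not None:
            mentions.append(
                EntityMention(
                    category=open_cat,
                    token_start=open_start,
                    token_end=end,
                    paragraph_id=paragraph.paragraph_id,
                    mention_id=f"{paragraph.paragraph_id}:m{len(mentions)}",
                    surface=paragraph.surface_of((open_start, end)),
                )
            )
            open_cat = None

    for i, tag in enumerate(tags):
        if tag == "O":
            close(i)
            continue
        pos, cat = tag[0], tag[1]
        if pos == "B":
            close(i)
            open_cat, open_start = cat, i
        elif pos == "I":
            if open_cat != cat:
                if strict:
                    raise DecodingError(
                        f"orphan continuation tag {tag!r} at index {i}"
                    )
                close(i)
                open_cat, open_start = cat, i
        else:  # "E"
            if open_cat == cat:
                close(i + 1)
            elif strict:
                raise DecodingError(f"orphan end tag {tag!r} at index {i}")
            else:
                close(i)
                open_cat, open_start = cat, i
                close(i + 1)
    close(len(tags))
    return mentions


def encode_mentions(tokens: list[Token], mentions: list[EntityMention]) -> list[str]:
    """Inverse of :func:`decode_tags`: write BIOE tags for the given spans."""
    n = len(tokens)
    tags = ["O"] * n
    occupied = [False] * n
    for m in sorted(mentions, key=lambda m: m.token_start):
        if m.token_end > n:
            raise SchemaError(
                f"mention {m.span} outside token range of length {n}"
            )
        if any(occupied[m.token_start : m.token_end]):
            raise SchemaError(f"overlapping mention at {m.span}")
        for i in range(m.token_start, m.token_end):
            occupied[i] = True
        width = m.token_end - m.token_start
        tags[m.token_start] = "B" + m.category
        if width > 1:
            tags[m.token_end - 1] = "E" + m.category
            for i in range(m.token_start + 1, m.token_end - 1):
                tags[i] = "I" + m.category
    return tags


# --- CoNLL-style corpus files -------------------------------------------
#
# Two columns (token TAB tag); blank line = sentence break; a line
# beginning with "-DOCSTART-" carries the paragraph id and separates
# paragraphs.  Character offsets are reconstructed by single-space
# joining, which is how the synthetic corpus lays text out.

_DOCSTART = "-DOCSTART-"


def write_conll(paragraphs: list[AnnotatedParagraph], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for para in paragraphs:
            fh.write(f"{_DOCSTART} {para.paragraph_id}\n")
            for si, (start, end) in enumerate(para.sentences):
                if si:
                    fh.write("\n")
                for i in range(start, end):
                    fh.write(f"{para.tokens[i].text}\t{para.tags[i]}\n")
            fh.write("\n")


def read_conll(path) -> list[AnnotatedParagraph]:
    paragraphs: list[AnnotatedParagraph] = []
    cur_id: str | None = None
    words: list[str] = []
    tags: list[str] = []
    sentences: list[tuple[int, int]] = []
    sent_start = 0

    def close_sentence() -> None:
        nonlocal sent_start
        if len(words) > sent_start:
            sentences.append((sent_start, len(words)))
            sent_start = len(words)

    def close_paragraph() -> None:
        nonlocal words, tags, sentences, sent_start
        close_sentence()
        if cur_id is not None:
            paragraphs.append(
                AnnotatedParagraph(
                    paragraph_id=cur_id,
                    tokens=tokens_from_strings(words),
                    tags=tags,
                    sentences=sentences,
                )
            )
        words, tags, sentences, sent_start = [], [], [], 0

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith(_DOCSTART):
                close_paragraph()
                cur_id = line[len(_DOCSTART) :].strip() or f"p{len(paragraphs)}"
            elif not line.strip():
                close_sentence()
            else:
                cols = line.split("\t")
                if len(cols) != 2:
                    raise ParseError(
                        f"line {lineno}: expected 2 tab-separated columns, "
                        f"got {len(cols)}",
                        line_number=lineno,
                    )
                if cur_id is None:
                    raise ParseError(
                        f"line {lineno}: token line before any {_DOCSTART}",
                        line_number=lineno,
                    )
                words.append(cols[0])
                tags.append(cols[1])
    close_paragraph()
    return paragraphs


def write_json(paragraphs: list[AnnotatedParagraph], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([p.to_json() for p in paragraphs], fh, indent=1)


def read_json(path) -> list[AnnotatedParagraph]:
    with open(path, encoding="utf-8") as fh:
        return [AnnotatedParagraph.from_json(o) for o in json.load(fh)]


def split_corpus(
    paragraphs: list[AnnotatedParagraph],
    ratio: tuple[int, int] = (10, 1),
    seed: int = 0,
) -> CorpusSplit:
    """Randomly partition paragraphs into train/validation at ``ratio``.

    The split is paragraph-level, so every derived relation record
    inherits its paragraph's side and the validation set cannot leak into
    training.  Validation size is nearest-integer ``n * b / (a + b)``
    with a floor of 1.  Deterministic for a given seed.
    """
    a, b = ratio
    if a <= 0 or b <= 0:
        raise ValueError(f"ratio parts must be positive, got {ratio}")
    if len(paragraphs) < 2:
        raise ValueError("need at least 2 paragraphs to split")
    ids = [p.paragraph_id for p in paragraphs]
    if len(set(ids)) != len(ids):
        raise SchemaError("duplicate paragraph ids")
    rng = random.Random(seed)
    shuffled = ids[:]
    rng.shuffle(shuffled)
    n_val = max(1, int(len(ids) * b / (a + b) + 0.5))
    val = shuffled[:n_val]
    train = shuffled[n_val:]
    return CorpusSplit(
        train=tuple(sorted(train)),
        validation=tuple(sorted(val)),
        seed=seed,
        ratio=(a, b),
    )


__all__ = [
    "CATEGORIES",
    "Token",
    "EntityMention",
    "AnnotatedParagraph",
    "CorpusSplit",
    "SchemaError",
    "DecodingError",
    "ParseError",
    "validate_tags",
    "tokens_from_strings",
    "decode_tags",
    "encode_mentions",
    "read_conll",
    "write_conll",
    "read_json",
    "write_json",
    "split_corpus",
]
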