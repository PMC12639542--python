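"""Contextual-embedding contract shared by both learned models.

Both the sentence-level relation classifier and the paragraph-level GCN
consume an :class:`EncodedSequence`: one d-dimensional vector per token
plus a sequence-level summary vector.  The default implementation is a
deterministic seeded hash encoder — every distinct token string maps to
a fixed pseudo-random unit-scale vector — which makes the whole pipeline
runnable and exactly reproducible on a single CPU with no downloads.
A pretrained-transformer adapter with the same interface is provided for
installations that have ``transformers`` available; it defaults to
frozen weights.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .corpus import Token


@dataclass
class EncodedSequence:
    """Per-token vectors plus a sequence-level summary vector."""

    token_vectors: np.ndarray  # (n_tokens, d)
    summary_vector: np.ndarray  # (d,)
    d: int

    def __post_init__(self):
        if self.token_vectors.ndim != 2 or self.token_vectors.shape[1] != self.d:
            raise ValueError("token_vectors must be (n, d)")
        if not np.all(np.isfinite(self.token_vectors)):
            raise ValueError("non-finite token vectors")


def span_mask(n_tokens: int, start: int, end: int) -> np.ndarray:
    """Binary mask over tokens selecting the half-open span [start, end)."""
    if not (0 <= start < end <= n_tokens):
        raise ValueError(f"invalid span [{start}, {end}) for {n_tokens} tokens")
    mask = np.zeros(n_tokens, dtype=np.float64)
    mask[start:end] = 1.0
    return mask


def pool_mask(enc: EncodedSequence, mask: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the token vectors selected by a binary mask."""
    mask = np.asarray(mask, dtype=np.float64)
    if mask.shape != (enc.token_vectors.shape[0],):
        raise ValueError(
            f"mask length {mask.shape} does not match "
            f"{enc.token_vectors.shape[0]} tokens"
        )
    total = mask.sum()
    if total < 1:
        raise ValueError("empty mask: span selects no tokens")
    return (mask @ enc.token_vectors) / total


class HashEncoder:
    """Deterministic per-token embedding from a keyed hash.

    Each distinct token string is hashed (BLAKE2b keyed by the seed) to
    seed a NumPy generator that draws its vector from N(0, 1/d).  The
    summary vector is the mean of the token vectors.  Identical
    (tokens, seed, d) inputs always produce identical output, across
    processes and platforms.
    """

    def __init__(self, d: int = 768, seed: int = 0):
        if d < 1:
            raise ValueError("embedding width d must be >= 1")
        self.d = d
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    def _vector(self, text: str) -> np.ndarray:
        vec = self._cache.get(text)
        if vec is None:
            digest = hashlib.blake2b(
                text.encode("utf-8"),
                key=str(self.seed).encode("utf-8"),
                digest_size=8,
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            vec = rng.standard_normal(self.d) / np.sqrt(self.d)
            self._cache[text] = vec
        return vec

    def encode(self, tokens: list[Token]) -> EncodedSequence:
        if not tokens:
            raise ValueError("cannot encode an empty token list")
        mat = np.stack([self._vector(t.text) for t in tokens])
        return EncodedSequence(
            token_vectors=mat, summary_vector=mat.mean(axis=0), d=self.d
        )


class TransformerEncoder:
    """Adapter wrapping a pretrained transformer (optional dependency).

    Uses the model's last hidden states as token vectors (whole-token
    pooling over subwords) and the first-position output as the summary
    vector.  Weights are frozen by default.  Requires the
    ``transformers`` and ``torch`` packages.
    """

    def __init__(self, model_name: str = "bert-base-uncased"):
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - optional path
            raise ImportError(
                "TransformerEncoder requires the optional 'transformers' and "
                "'torch' packages; install them or use HashEncoder"
            ) from exc
        self._tokenizer = AutoTokenizer.from_pretrained(model_name)
        self._model = AutoModel.from_pretrained(model_name)
        self._model.eval()
        self.d = self._model.config.hidden_size

    def encode(self, tokens: list[Token]) -> EncodedSequence:  # pragma: no cover
        import torch

        words = [t.text for t in tokens]
        if not words:
            raise ValueError("cannot encode an empty token list")
        batch = self._tokenizer(
            words, is_split_into_words=True, return_tensors="pt", truncation=True
        )
        with torch.no_grad():
            hidden = self._model(**batch).last_hidden_state[0].numpy()
        word_ids = batch.word_ids(0)
        mat = np.zeros((len(words), self.d))
        counts = np.zeros(len(words))
        for pos, wid in enumerate(word_ids):
            if wid is not None:
                mat[wid] += hidden[pos]
                counts[wid] += 1
        counts[counts == 0] = 1
        mat /= counts[:, None]
        return EncodedSequence(
            token_vectors=mat, summary_vector=hidden[0], d=self.d
        )


def make_encoder(config: dict):
    """Build an encoder from a config block ``{type, d, seed, model_name}``."""
    kind = config.get("type", "hash")
    if kind == "hash":
        return HashEncoder(d=config.get("d", 768), seed=config.get("seed", 0))
    if kind == "transformer":
        return TransformerEncoder(config.get("model_name", "bert-base-uncased"))
    raise ValueError(f"unknown encoder type {kind!r}")


__all__ = [
    "EncodedSequence",
    "HashEncoder",
    "TransformerEncoder",
    "span_mask",
    "pool_mask",
    "make_encoder",
]
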