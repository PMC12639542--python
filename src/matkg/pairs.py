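"""Typed entity-pair candidate generation for sentence-level relation extraction.

Every unordered pair of the six entity categories maps to exactly one
policy:

* ``CLASSIFY`` — emit the pair as a candidate for the binary relation
  classifier;
* ``ALWAYS_LINK`` — emit it pre-labeled positive (for pair types with
  essentially no negative examples);
* ``EXCLUDE`` — never emit it (semantically impossible pairs, plus
  material–material pairs, which are the paragraph-level model's task).

Candidates are sentence-scoped except for the M–M experimental-step
chain, which links step mentions across sentences.
"""

from __future__ import annotations

import itertools
import json
import random
from dataclasses import dataclass
from enum import Enum

from .corpus import AnnotatedParagraph, EntityMention

#: Category precedence used to canonicalize pair-type names (EM not ME).
_PAIR_ORDER = {c: i for i, c in enumerate("EMCRDV")}


class Policy(Enum):
    CLASSIFY = "classify"
    ALWAYS_LINK = "always_link"
    EXCLUDE = "exclude"


def pair_type(cat_a: str, cat_b: str) -> str:
    """Canonical unordered pair-type name, e.g. ``("C", "M") -> "MC"``."""
    return "".join(sorted((cat_a, cat_b), key=_PAIR_ORDER.__getitem__))


def all_pair_types() -> list[str]:
    """All 21 unordered category pairs (including same-category pairs)."""
    cats = sorted(_PAIR_ORDER, key=_PAIR_ORDER.__getitem__)
    return [pair_type(a, b) for a, b in
            itertools.combinations_with_replacement(cats, 2)]


def default_policy_table(always_link_preset: bool = False) -> dict[str, Policy]:
    """Policy for every unordered category pair.

    ``MV``, ``RD`` and ``CV`` are excluded as semantically unconnected;
    ``EE`` (material–material) is excluded here because cross-material
    relations are resolved at paragraph level.  With
    ``always_link_preset`` the pair types that carry almost no negative
    examples (``ER``, ``EM``, ``RV``) are auto-linked instead of
    classified.
    """
    table = {pt: Policy.CLASSIFY for pt in all_pair_types()}
    for pt in ("MV", "RD", "CV", "EE"):
        table[pt] = Policy.EXCLUDE
    if always_link_preset:
        for pt in ("ER", "EM", "RV"):
            table[pt] = Policy.ALWAYS_LINK
    return table


@dataclass(frozen=True)
class RelationInstance:
    """One ordered mention pair with a pair type and binary label.

    ``label`` is 1 (relevant) or ``None`` (irrelevant / not yet
    predicted), following the corpus convention.  ``mention_a`` precedes
    ``mention_b`` in token order.  ``sentence_index`` is the sentence of
    ``mention_a``; only M–M chain instances may span sentences.
    """

    paragraph_id: str
    sentence_index: int
    mention_a: EntityMention
    mention_b: EntityMention
    pair_type: str
    label: int | None = None
    probability: float | None = None

    def key(self) -> tuple:
        return (self.paragraph_id, self.mention_a.span, self.mention_b.span)

    def to_json(self) -> dict:
        def span(m: EntityMention) -> dict:
            return {"category": m.category, "start": m.token_start,
                    "end": m.token_end, "surface": m.surface}

        return {
            "paragraph_id": self.paragraph_id,
            "sentence_index": self.sentence_index,
            "mention_a": span(self.mention_a),
            "mention_b": span(self.mention_b),
            "pair_type": self.pair_type,
            "label": self.label,
            "probability": self.probability,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "RelationInstance":
        def mention(d: dict) -> EntityMention:
            return EntityMention(
                category=d["category"], token_start=d["start"],
                token_end=d["end"], paragraph_id=obj["paragraph_id"],
                surface=d.get("surface", ""),
            )

        return cls(
            paragraph_id=obj["paragraph_id"],
            sentence_index=obj["sentence_index"],
            mention_a=mention(obj["mention_a"]),
            mention_b=mention(obj["mention_b"]),
            pair_type=obj["pair_type"],
            label=obj["label"],
            probability=obj.get("probability"),
        )


def build_candidates(
    paragraph: AnnotatedParagraph,
    policy: dict[str, Policy] | None = None,
    gold: set[tuple[tuple[int, int], tuple[int, int]]] | None = None,
) -> list[RelationInstance]:
    """Emit one candidate per same-sentence mention pair allowed by ``policy``.

    ``gold``, when given, is the set of positive ``(span_a, span_b)``
    pairs (token spans, a before b); matching candidates are labeled 1
    and the rest ``None`` (irrelevant).  Without ``gold`` all CLASSIFY
    candidates are unlabeled, pending prediction.  ALWAYS_LINK
    candidates are emitted pre-labeled 1 either way.
    """
    if policy is None:
        policy = default_policy_table()
    out: list[RelationInstance] = []
    mentions = sorted(paragraph.get_mentions(), key=lambda m: m.token_start)
    for si, (start, end) in enumerate(paragraph.sentences):
        in_sent = [m for m in mentions if start <= m.token_start and m.token_end <= end]
        for a, b in itertools.combinations(in_sent, 2):
            pt = pair_type(a.category, b.category)
            pol = policy[pt]
            if pol is Policy.EXCLUDE:
                continue
            if pol is Policy.ALWAYS_LINK:
                label = 1
            elif gold is not None:
                label = 1 if (a.span, b.span) in gold else None
            else:
                label = None
            out.append(RelationInstance(
                paragraph_id=paragraph.paragraph_id, sentence_index=si,
                mention_a=a, mention_b=b, pair_type=pt, label=label,
            ))
    return out


def chain_steps(
    paragraph: AnnotatedParagraph,
    gold_chain: list[tuple[int, int]] | None = None,
) -> list[RelationInstance]:
    """Candidate M–M pairs linking experimental steps across the paragraph.

    ``gold_chain`` is the ordered list of step-mention token spans in
    true experimental order (generator metadata for synthetic data, or
    curation for real data); pairs adjacent in the chain are labeled 1.
    The chain is *not* assumed to follow token order — step sentences
    may be narrated out of sequence.
    """
    steps = sorted(
        (m for m in paragraph.get_mentions() if m.category == "M"),
        key=lambda m: m.token_start,
    )
    adjacent: set[frozenset] = set()
    if gold_chain is not None:
        for u, v in zip(gold_chain, gold_chain[1:]):
            adjacent.add(frozenset((u, v)))
    out = []
    for a, b in itertools.combinations(steps, 2):
        label: int | None
        if gold_chain is None:
            label = None
        else:
            label = 1 if frozenset((a.span, b.span)) in adjacent else None
        out.append(RelationInstance(
            paragraph_id=paragraph.paragraph_id,
            sentence_index=paragraph.sentence_of(a.token_start),
            mention_a=a, mention_b=b, pair_type="MM", label=label,
        ))
    return out


def subsample_negatives(
    instances: list[RelationInstance], ratio: float = 3.0, seed: int = 0
) -> list[RelationInstance]:
    """Keep all positives and at most ``ratio`` negatives per positive.

    Mitigates the class imbalance of automatically generated candidate
    sets.  Deterministic for a given seed; output preserves input order.
    """
    positives = [i for i in instances if i.label == 1]
    negatives = [i for i in instances if i.label != 1]
    cap = int(round(len(positives) * ratio))
    if len(negatives) > cap:
        rng = random.Random(seed)
        keep = set(rng.sample(range(len(negatives)), cap))
        negatives = [x for j, x in enumerate(negatives) if j in keep]
    kept = set(map(id, positives)) | set(map(id, negatives))
    return [i for i in instances if id(i) in kept]


def write_jsonl(instances: list[RelationInstance], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            fh.write(json.dumps(inst.to_json()) + "\n")


def read_jsonl(path) -> list[RelationInstance]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(RelationInstance.from_json(json.loads(line)))
    return out


__all__ = [
    "Policy",
    "RelationInstance",
    "pair_type",
    "all_pair_types",
    "default_policy_table",
    "build_candidates",
    "chain_steps",
    "subsample_negatives",
    "write_jsonl",
    "read_jsonl",
]
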