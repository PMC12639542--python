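"""Binary sentence-level relation classifier over typed mention pairs.

The feature vector for a candidate pair is the 3d concatenation of the
mask-averaged embedding of entity A, the sequence summary vector, and
the mask-averaged embedding of entity B, fed to a small fully connected
head with two output classes (related / unrelated).  One shared model
serves all classified pair types; the candidate sets of the different
pair types are pooled for training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from ._nn import MLPClassifier
from .corpus import AnnotatedParagraph
from .encoders import EncodedSequence, pool_mask, span_mask
from .pairs import RelationInstance, Policy, default_policy_table, pair_type


def featurize_pair(enc: EncodedSequence, mask_a: np.ndarray,
                   mask_b: np.ndarray) -> np.ndarray:
    """Concatenate (entity-A pool, summary vector, entity-B pool)."""
    mask_a = np.asarray(mask_a, dtype=np.float64)
    mask_b = np.asarray(mask_b, dtype=np.float64)
    if np.any((mask_a > 0) & (mask_b > 0)):
        raise ValueError("entity masks overlap")
    return np.concatenate(
        [pool_mask(enc, mask_a), enc.summary_vector, pool_mask(enc, mask_b)]
    )


def _window(paragraph: AnnotatedParagraph, inst: RelationInstance) -> tuple[int, int]:
    """Token window covering the sentences of both mentions.

    For same-sentence candidates this is the sentence itself; for M–M
    chain instances it spans from the first mention's sentence to the
    second's.
    """
    sa = paragraph.sentence_of(inst.mention_a.token_start)
    sb = paragraph.sentence_of(inst.mention_b.token_start)
    start = paragraph.sentences[min(sa, sb)][0]
    end = paragraph.sentences[max(sa, sb)][1]
    return start, end


def featurize_instance(inst: RelationInstance, paragraph: AnnotatedParagraph,
                       encoder) -> np.ndarray:
    start, end = _window(paragraph, inst)
    enc = encoder.encode(paragraph.tokens[start:end])
    n = end - start
    mask_a = span_mask(n, inst.mention_a.token_start - start,
                       inst.mention_a.token_end - start)
    mask_b = span_mask(n, inst.mention_b.token_start - start,
                       inst.mention_b.token_end - start)
    return featurize_pair(enc, mask_a, mask_b)


@dataclass
class SentenceREConfig:
    hidden: int = 64
    dropout: float = 0.1
    epochs: int = 40
    lr: float = 1e-3
    batch_size: int = 64
    weight_decay: float = 1e-4
    seed: int = 0


@dataclass
class SentenceREModel:
    head: MLPClassifier
    d: int
    config: SentenceREConfig

    def save(self, path) -> None:
        obj = {"d": self.d, "config": vars(self.config),
               "head": self.head.to_json()}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh)

    @classmethod
    def load(cls, path) -> "SentenceREModel":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls(head=MLPClassifier.from_json(obj["head"]), d=obj["d"],
                   config=SentenceREConfig(**obj["config"]))


def _design_matrix(instances, paragraphs, encoder):
    by_id = {p.paragraph_id: p for p in paragraphs}
    X = np.stack([
        featurize_instance(inst, by_id[inst.paragraph_id], encoder)
        for inst in instances
    ])
    return X


def train_sentence_re(
    instances: list[RelationInstance],
    paragraphs: list[AnnotatedParagraph],
    encoder,
    config: SentenceREConfig | None = None,
    val_instances: list[RelationInstance] | None = None,
    val_paragraphs: list[AnnotatedParagraph] | None = None,
):
    """Train the shared binary head on labeled candidates.

    Returns ``(model, report)`` where ``report`` is the evaluation
    module's :class:`MetricReport` on the validation instances (or on
    the training instances when no validation set is given).
    Deterministic given ``config.seed``.
    """
    from .evaluation import score

    config = config or SentenceREConfig()
    y = np.array([1 if inst.label == 1 else 0 for inst in instances])
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    X = _design_matrix(instances, paragraphs, encoder)
    head = MLPClassifier(X.shape[1], config.hidden, 2,
                         dropout=config.dropout, seed=config.seed)
    head.fit(X, y, epochs=config.epochs, lr=config.lr,
             batch_size=config.batch_size, weight_decay=config.weight_decay)
    model = SentenceREModel(head=head, d=encoder.d, config=config)

    if val_instances:
        eval_insts, eval_paras = val_instances, (val_paragraphs or paragraphs)
    else:
        eval_insts, eval_paras = instances, paragraphs
    predicted = predict_pairs(model, eval_insts, eval_paras, encoder)
    gold = [1 if i.label == 1 else 0 for i in eval_insts]
    pred = [1 if i.label == 1 else 0 for i in predicted]
    return model, score(gold, pred)


def predict_pairs(
    model: SentenceREModel,
    instances: list[RelationInstance],
    paragraphs: list[AnnotatedParagraph],
    encoder,
    policy=None,
) -> list[RelationInstance]:
    """Label every candidate: ALWAYS_LINK pairs pass through as positive,
    CLASSIFY pairs get the head's decision (ties at p=0.5 stay unlinked)."""
    if not instances:
        return []
    if policy is None:
        policy = default_policy_table()
    out: list[RelationInstance] = []
    classify = [i for i in instances
                if policy.get(i.pair_type, Policy.CLASSIFY) is Policy.CLASSIFY]
    probs_by_key = {}
    if classify:
        X = _design_matrix(classify, paragraphs, encoder)
        probs = model.head.predict_proba(X)[:, 1]
        probs_by_key = {inst.key(): float(p) for inst, p in zip(classify, probs)}
    for inst in instances:
        pol = policy.get(inst.pair_type, Policy.CLASSIFY)
        if pol is Policy.ALWAYS_LINK:
            out.append(replace(inst, label=1, probability=1.0))
        else:
            p = probs_by_key[inst.key()]
            out.append(replace(inst, label=1 if p > 0.5 else None,
                               probability=p))
    return out


__all__ = [
    "SentenceREConfig",
    "SentenceREModel",
    "featurize_pair",
    "featurize_instance",
    "train_sentence_re",
    "predict_pairs",
]
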