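"""Paragraph-level relation classification between two material entities.

Sentence-level classification cannot decide how two *materials* relate
("the solution" may name a product two sentences before it exists), so
material pairs are classified at paragraph scope over a mention graph:

* nodes — every mention of material A and every mention of material B,
  in document order;
* edges — consecutive alternating appearances: each adjacent (A, B) or
  (B, A) pair in the merged mention order is joined, and the edge is
  embedded from the text between the two mentions (falling back to the
  union of the mention spans when they are adjacent).

Node features start as mask-averaged token embeddings and are updated
by a graph convolution with symmetric normalization
``D^{-1/2} (A + I) D^{-1/2}`` and one weight matrix shared by both
materials' nodes; edge features are updated by an independent affine
map.  After every stage (including stage 0) the A-node mean, edge mean
and B-node mean are concatenated, and a linear softmax head scores the
four labels: A includes B, B includes A, unrelated, identical.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import numpy as np

from ._nn import AdamW, glorot, relu, softmax
from .corpus import AnnotatedParagraph, EntityMention
from .encoders import EncodedSequence, pool_mask, span_mask

PARA_LABELS = ("A_INCLUDES_B", "B_INCLUDES_A", "UNRELATED", "IDENTICAL")
_LABEL_INDEX = {lab: i for i, lab in enumerate(PARA_LABELS)}

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Material-name normalization: trim, collapse whitespace, casefold."""
    return _WS.sub(" ", name.strip()).casefold()


def group_materials(paragraph: AnnotatedParagraph) -> dict[str, list[EntityMention]]:
    """Group the paragraph's E-mentions by normalized surface form."""
    groups: dict[str, list[EntityMention]] = {}
    for m in paragraph.get_mentions():
        if m.category == "E":
            groups.setdefault(normalize_name(m.surface), []).append(m)
    for v in groups.values():
        v.sort(key=lambda m: m.token_start)
    return groups


def candidate_material_pairs(paragraph: AnnotatedParagraph) -> list[tuple[str, str]]:
    """All unordered pairs of distinct material names in the paragraph."""
    names = sorted(group_materials(paragraph))
    return [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]


@dataclass
class MentionGraph:
    """Mention nodes of two materials plus alternating-appearance edges.

    Node order is all A-mentions then all B-mentions (each in document
    order); ``edges`` holds ``(node_index, node_index)`` pairs joining
    one A-node and one B-node, with a token mask per edge.
    """

    paragraph_id: str
    material_a: str
    material_b: str
    nodes_a: list[EntityMention]
    nodes_b: list[EntityMention]
    edges: list[tuple[int, int]]
    node_masks: list[np.ndarray]
    edge_masks: list[np.ndarray]
    n_tokens: int

    @property
    def n_nodes(self) -> int:
        return len(self.nodes_a) + len(self.nodes_b)

    @property
    def a_indices(self) -> np.ndarray:
        return np.arange(len(self.nodes_a))

    @property
    def b_indices(self) -> np.ndarray:
        return np.arange(len(self.nodes_a), self.n_nodes)


def build_mention_graph(
    paragraph: AnnotatedParagraph, material_a: str, material_b: str
) -> MentionGraph:
    """Build the alternating-appearance mention graph for two materials.

    Consecutive mentions of opposite materials (no intervening mention
    of either) are joined; when all A-mentions precede all B-mentions
    this still yields one edge, between the last A and the first B.
    Each edge's mask covers the tokens strictly between its two
    mentions, or the union of the mention spans when the gap is empty.
    """
    groups = group_materials(paragraph)
    key_a, key_b = normalize_name(material_a), normalize_name(material_b)
    for key in (key_a, key_b):
        if key not in groups or not groups[key]:
            raise ValueError(
                f"material {key!r} has no mention in paragraph "
                f"{paragraph.paragraph_id}"
            )
    nodes_a, nodes_b = groups[key_a], groups[key_b]
    n = len(paragraph.tokens)

    merged = [(m, 0, i) for i, m in enumerate(nodes_a)]
    merged += [(m, 1, i) for i, m in enumerate(nodes_b)]
    merged.sort(key=lambda t: t[0].token_start)

    edges: list[tuple[int, int]] = []
    edge_masks: list[np.ndarray] = []
    offset_b = len(nodes_a)
    for (m1, side1, i1), (m2, side2, i2) in zip(merged, merged[1:]):
        if side1 == side2:
            continue
        u = i1 if side1 == 0 else offset_b + i1
        v = i2 if side2 == 0 else offset_b + i2
        if m1.token_end < m2.token_start:
            mask = span_mask(n, m1.token_end, m2.token_start)
        else:
            mask = span_mask(n, m1.token_start, m1.token_end)
            mask += span_mask(n, m2.token_start, m2.token_end)
            mask = np.minimum(mask, 1.0)
        edges.append((u, v))
        edge_masks.append(mask)

    node_masks = [span_mask(n, m.token_start, m.token_end)
                  for m in nodes_a + nodes_b]
    return MentionGraph(
        paragraph_id=paragraph.paragraph_id,
        material_a=key_a, material_b=key_b,
        nodes_a=nodes_a, nodes_b=nodes_b,
        edges=edges, node_masks=node_masks, edge_masks=edge_masks,
        n_tokens=n,
    )


@dataclass
class GraphState:
    """Node and edge feature matrices after ``layer`` convolutions."""

    H_node: np.ndarray  # (n_nodes, d)
    H_edge: np.ndarray  # (n_edges, d)
    layer: int = 0


@dataclass
class GCNLayerParams:
    """One convolution stage: shared node weight, edge affine map."""

    W_node: np.ndarray
    W_edge: np.ndarray
    b_edge: np.ndarray


def normalized_adjacency(graph: MentionGraph) -> np.ndarray:
    """Symmetric-normalized adjacency with self-loops over all nodes."""
    n = graph.n_nodes
    A = np.zeros((n, n))
    for u, v in graph.edges:
        A[u, v] = A[v, u] = 1.0
    A_hat = A + np.eye(n)
    d_inv_sqrt = 1.0 / np.sqrt(A_hat.sum(axis=1))
    return A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def embed_graph(graph: MentionGraph, enc: EncodedSequence) -> GraphState:
    """Stage-0 features: mask-mean embeddings for every node and edge."""
    H_node = np.stack([pool_mask(enc, m) for m in graph.node_masks])
    if graph.edges:
        H_edge = np.stack([pool_mask(enc, m) for m in graph.edge_masks])
    else:
        H_edge = np.zeros((0, enc.d))
    return GraphState(H_node=H_node, H_edge=H_edge, layer=0)


def gcn_layer(state: GraphState, S: np.ndarray,
              params: GCNLayerParams, activation=relu) -> GraphState:
    """One shared-weight convolution plus the edge affine update."""
    if S.shape[0] != state.H_node.shape[0]:
        raise ValueError("adjacency size does not match node count")
    if params.W_node.shape[0] != state.H_node.shape[1]:
        raise ValueError("weight width does not match feature width")
    H_node = activation(S @ state.H_node @ params.W_node)
    H_edge = activation(state.H_edge @ params.W_edge + params.b_edge)
    return GraphState(H_node=H_node, H_edge=H_edge, layer=state.layer + 1)


def mirror_permutation(d: int, n_layers: int) -> np.ndarray:
    """Feature-index permutation that swaps the A and B blocks per stage."""
    perm = np.arange(3 * d * (n_layers + 1))
    for stage in range(n_layers + 1):
        off = 3 * d * stage
        a = perm[off:off + d].copy()
        perm[off:off + d] = perm[off + 2 * d:off + 3 * d]
        perm[off + 2 * d:off + 3 * d] = a
    return perm


@dataclass
class ParaLabel:
    label: str
    probabilities: np.ndarray

    def __post_init__(self):
        if self.label not in PARA_LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class MaterialPairRecord:
    """A labeled (or to-be-labeled) material pair within one paragraph."""

    paragraph_id: str
    material_a: str
    material_b: str
    label: str | None = None
    probabilities: tuple[float, ...] | None = None

    def to_json(self) -> dict:
        return {
            "paragraph_id": self.paragraph_id,
            "material_a": self.material_a,
            "material_b": self.material_b,
            "label": self.label,
            "probabilities": list(self.probabilities) if self.probabilities else None,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "MaterialPairRecord":
        probs = obj.get("probabilities")
        return cls(
            paragraph_id=obj["paragraph_id"],
            material_a=obj["material_a"], material_b=obj["material_b"],
            label=obj.get("label"),
            probabilities=tuple(probs) if probs else None,
        )


def write_pairs_jsonl(records, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_json()) + "\n")


def read_pairs_jsonl(path) -> list[MaterialPairRecord]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(MaterialPairRecord.from_json(json.loads(line)))
    return out


@dataclass
class ParaGCNConfig:
    n_layers: int = 2
    epochs: int = 60
    lr: float = 2e-3
    batch_size: int = 16
    weight_decay: float = 1e-4
    seed: int = 0


class ParaGCNModel:
    """Shared-weight GCN plus linear softmax head over stage averages."""

    def __init__(self, d: int, config: ParaGCNConfig):
        self.d = d
        self.config = config
        self.trained = False
        rng = np.random.default_rng(config.seed)
        L = config.n_layers
        self.params: dict[str, np.ndarray] = {}
        for l in range(1, L + 1):
            self.params[f"Wn{l}"] = glorot(rng, d, d)
            self.params[f"We{l}"] = glorot(rng, d, d)
            self.params[f"be{l}"] = np.zeros(d)
        n_feat = 3 * d * (L + 1)
        self.params["Wc"] = glorot(rng, n_feat, len(PARA_LABELS))
        self.params["bc"] = np.zeros(len(PARA_LABELS))

    @property
    def n_layers(self) -> int:
        return self.config.n_layers

    def layer_params(self, l: int) -> GCNLayerParams:
        return GCNLayerParams(
            W_node=self.params[f"Wn{l}"],
            W_edge=self.params[f"We{l}"],
            b_edge=self.params[f"be{l}"],
        )

    # -- forward -----------------------------------------------------

    def _forward(self, X0, E0, S, a_idx, b_idx):
        """Run all stages; returns (features, cache for backprop)."""
        L = self.n_layers
        Xs, Es, Zs, Fs, Ms = [X0], [E0], [None], [None], [None]
        for l in range(1, L + 1):
            M = S @ Xs[-1]
            Z = M @ self.params[f"Wn{l}"]
            F = Es[-1] @ self.params[f"We{l}"] + self.params[f"be{l}"]
            Xs.append(relu(Z))
            Es.append(relu(F))
            Zs.append(Z)
            Fs.append(F)
            Ms.append(M)
        feats = []
        for l in range(L + 1):
            a_mean = Xs[l][a_idx].mean(axis=0)
            e_mean = (Es[l].mean(axis=0) if Es[l].shape[0]
                      else np.zeros(self.d))
            b_mean = Xs[l][b_idx].mean(axis=0)
            feats.extend([a_mean, e_mean, b_mean])
        h = np.concatenate(feats)
        cache = (Xs, Es, Zs, Fs, Ms, S, a_idx, b_idx)
        return h, cache

    def features(self, graph: MentionGraph, enc: EncodedSequence) -> np.ndarray:
        state = embed_graph(graph, enc)
        S = normalized_adjacency(graph)
        h, _ = self._forward(state.H_node, state.H_edge, S,
                             graph.a_indices, graph.b_indices)
        return h

    def predict_proba(self, graph: MentionGraph, enc: EncodedSequence) -> np.ndarray:
        h = self.features(graph, enc)
        logits = h @ self.params["Wc"] + self.params["bc"]
        return softmax(logits)

    # -- backward ----------------------------------------------------

    def _backward(self, dlogits, h, cache, grads):
        Xs, Es, Zs, Fs, Ms, S, a_idx, b_idx = cache
        L = self.n_layers
        d = self.d
        grads["Wc"] += np.outer(h, dlogits)
        grads["bc"] += dlogits
        dh = self.params["Wc"] @ dlogits

        dX_direct = [np.zeros_like(Xs[l]) for l in range(L + 1)]
        dE_direct = [np.zeros_like(Es[l]) for l in range(L + 1)]
        for l in range(L + 1):
            off = 3 * d * l
            da = dh[off:off + d]
            de = dh[off + d:off + 2 * d]
            db = dh[off + 2 * d:off + 3 * d]
            dX_direct[l][a_idx] += da / len(a_idx)
            dX_direct[l][b_idx] += db / len(b_idx)
            if Es[l].shape[0]:
                dE_direct[l] += de / Es[l].shape[0]

        carry_X = np.zeros_like(Xs[L])
        carry_E = np.zeros_like(Es[L])
        for l in range(L, 0, -1):
            dX = dX_direct[l] + carry_X
            dZ = dX * (Zs[l] > 0)
            grads[f"Wn{l}"] += Ms[l].T @ dZ
            carry_X = S @ (dZ @ self.params[f"Wn{l}"].T)

            dE = dE_direct[l] + carry_E
            dF = dE * (Fs[l] > 0)
            grads[f"We{l}"] += Es[l - 1].T @ dF
            grads[f"be{l}"] += dF.sum(axis=0)
            carry_E = dF @ self.params[f"We{l}"].T

    # -- persistence -------------------------------------------------

    def save(self, path) -> None:
        obj = {"d": self.d, "config": vars(self.config),
               "trained": self.trained,
               "params": {k: v.tolist() for k, v in self.params.items()}}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh)

    @classmethod
    def load(cls, path) -> "ParaGCNModel":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        model = cls(obj["d"], ParaGCNConfig(**obj["config"]))
        model.params = {k: np.array(v) for k, v in obj["params"].items()}
        model.trained = obj["trained"]
        return model


def classify_material_pair(graph: MentionGraph, enc: EncodedSequence,
                           model: ParaGCNModel) -> ParaLabel:
    """Score one material pair; requires a trained model."""
    if not model.trained:
        raise ValueError("model has not been trained")
    probs = model.predict_proba(graph, enc)
    return ParaLabel(label=PARA_LABELS[int(np.argmax(probs))],
                     probabilities=probs)


def _prepare(records, paragraphs, encoder):
    by_id = {p.paragraph_id: p for p in paragraphs}
    prepared = []
    for rec in records:
        para = by_id[rec.paragraph_id]
        graph = build_mention_graph(para, rec.material_a, rec.material_b)
        enc = encoder.encode(para.tokens)
        state = embed_graph(graph, enc)
        S = normalized_adjacency(graph)
        prepared.append((state.H_node, state.H_edge, S,
                         graph.a_indices, graph.b_indices, rec.label))
    return prepared


def train_para_re(
    records: list[MaterialPairRecord],
    paragraphs: list[AnnotatedParagraph],
    encoder,
    config: ParaGCNConfig | None = None,
    val_records: list[MaterialPairRecord] | None = None,
    val_paragraphs: list[AnnotatedParagraph] | None = None,
):
    """Train the paragraph-level GCN classifier.

    All four labels must be present in training data.  Returns
    ``(model, report)`` with the evaluation module's multi-class metric
    report (including the confusion matrix) on the validation records,
    or on the training records when no validation set is given.
    Deterministic given ``config.seed``.
    """
    from .evaluation import score

    config = config or ParaGCNConfig()
    seen = {rec.label for rec in records}
    missing = set(PARA_LABELS) - seen
    if missing:
        raise ValueError(f"missing label classes in training data: {sorted(missing)}")

    prepared = _prepare(records, paragraphs, encoder)
    model = ParaGCNModel(encoder.d, config)
    opt = AdamW(model.params, lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)
    n = len(prepared)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            grads = {k: np.zeros_like(v) for k, v in model.params.items()}
            for i in idx:
                X0, E0, S, a_idx, b_idx, label = prepared[i]
                h, cache = model._forward(X0, E0, S, a_idx, b_idx)
                logits = h @ model.params["Wc"] + model.params["bc"]
                probs = softmax(logits)
                dlogits = probs.copy()
                dlogits[_LABEL_INDEX[label]] -= 1.0
                dlogits /= len(idx)
                model._backward(dlogits, h, cache, grads)
            opt.step(grads)
    model.trained = True

    eval_records = val_records if val_records else records
    eval_paras = (val_paragraphs or paragraphs) if val_records else paragraphs
    predicted = predict_material_pairs(model, eval_records, eval_paras, encoder)
    gold = [r.label for r in eval_records]
    pred = [r.label for r in predicted]
    report = score(gold, pred, labels=list(PARA_LABELS))
    return model, report


def predict_material_pairs(
    model: ParaGCNModel,
    records: list[MaterialPairRecord],
    paragraphs: list[AnnotatedParagraph],
    encoder,
) -> list[MaterialPairRecord]:
    by_id = {p.paragraph_id: p for p in paragraphs}
    out = []
    for rec in records:
        para = by_id[rec.paragraph_id]
        graph = build_mention_graph(para, rec.material_a, rec.material_b)
        enc = encoder.encode(para.tokens)
        result = classify_material_pair(graph, enc, model)
        out.append(MaterialPairRecord(
            paragraph_id=rec.paragraph_id,
            material_a=rec.material_a, material_b=rec.material_b,
            label=result.label,
            probabilities=tuple(float(p) for p in result.probabilities),
        ))
    return out


__all__ = [
    "PARA_LABELS",
    "MentionGraph",
    "GraphState",
    "GCNLayerParams",
    "ParaLabel",
    "MaterialPairRecord",
    "ParaGCNConfig",
    "ParaGCNModel",
    "normalize_name",
    "group_materials",
    "candidate_material_pairs",
    "build_mention_graph",
    "normalized_adjacency",
    "embed_graph",
    "gcn_layer",
    "mirror_permutation",
    "classify_material_pair",
    "train_para_re",
    "predict_material_pairs",
    "write_pairs_jsonl",
    "read_pairs_jsonl",
]
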