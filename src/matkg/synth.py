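"""Synthetic annotated corpus of materials-synthesis paragraphs.

Generates template-realized synthesis narratives (dissolve → stir → age
→ dry → calcine → characterize) over a mesoporous-bioactive-glass
vocabulary, with gold annotations for every pipeline stage: BIOE tags,
sentence-level relation labels, the experimental-step chain,
paragraph-level material-pair labels, and per-material structure
graphs.  The generator is the ground-truth oracle for the pipeline: at
zero label noise, running the rule engine on the gold relations must
reproduce the gold graphs exactly.

Label consistency is by construction: whether two entity surfaces are
related is a global property of the vocabulary (each step verb owns its
reagent and value pools, each reagent its amounts, each property its
values; distractor tokens are never related to anything), so the same
surface pair never appears with contradictory labels anywhere in a
corpus.  Coreference ("the sol" for the product) and general–specific
families ("bioactive glasses" ⊃ "MBG-58S glass") drive the four
paragraph-level labels.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from importlib import resources

from .corpus import AnnotatedParagraph, tokens_from_strings
from .pairs import RelationInstance, build_candidates, chain_steps
from .para_gcn import MaterialPairRecord, normalize_name
from .structuring import MaterialStructureGraph, NodeId

_PATTERNS = ("single", "alias", "general", "general_alias",
             "two_specific", "general_two")


def load_vocab() -> dict:
    """Load the editable template vocabulary shipped with the package."""
    with resources.files("matkg.data").joinpath("vocab.json").open(
            encoding="utf-8") as fh:
        return json.load(fh)


@dataclass
class GeneratorConfig:
    """Knobs for corpus synthesis.

    ``pattern_weights`` controls the material composition of paragraphs
    (how many materials, whether a coreferent alias or a general family
    term appears) and hence the paragraph-level label distribution;
    ``alternation_density`` is the probability that a non-product
    sentence is interleaved among the product's sentences, which tunes
    the mention-graph edge counts; ``distractor_rate`` injects
    unrelated reagent/value mentions that become negative relation
    candidates; ``label_noise`` flips gold labels (see
    :func:`corrupt_labels`).
    """

    n_paragraphs: int = 486
    min_steps: int = 3
    max_steps: int = 5
    alternation_density: float = 0.7
    distractor_rate: float = 0.5
    pattern_weights: dict = field(default_factory=lambda: {
        "single": 0.15, "alias": 0.20, "general": 0.20,
        "general_alias": 0.20, "two_specific": 0.15, "general_two": 0.10,
    })
    label_noise: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_paragraphs < 1:
            raise ValueError("n_paragraphs must be >= 1")
        if not (2 <= self.min_steps <= self.max_steps):
            raise ValueError("need 2 <= min_steps <= max_steps")
        if not self.pattern_weights or \
                any(w < 0 for w in self.pattern_weights.values()) or \
                sum(self.pattern_weights.values()) <= 0:
            raise ValueError("pattern_weights must be positive")
        if unknown := set(self.pattern_weights) - set(_PATTERNS):
            raise ValueError(f"unknown patterns {sorted(unknown)}")
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if not (0 <= self.alternation_density <= 1):
            raise ValueError("alternation_density must be in [0, 1]")


@dataclass
class GoldBundle:
    """One paragraph with gold data for every pipeline stage."""

    paragraph: AnnotatedParagraph
    relations: list[RelationInstance]
    pair_labels: list[MaterialPairRecord]
    graphs: dict[str, MaterialStructureGraph]
    merged: dict[NodeId, MaterialStructureGraph]
    chain: list[tuple[int, int]]
    flipped_relations: frozenset = frozenset()
    flipped_pairs: frozenset = frozenset()


class _Sentence:
    """A sentence under construction: tokens, tags, entity spans."""

    def __init__(self):
        self.tokens: list[str] = []
        self.tags: list[str] = []
        self.ents: list[tuple[str, int, int, str]] = []  # cat, start, end, surf
        self.pos_pairs: list[tuple[int, int]] = []  # indices into ents
        self.step_ent: int | None = None  # ents index of the M mention

    def words(self, *words: str) -> None:
        self.tokens.extend(words)
        self.tags.extend("O" for _ in words)

    def entity(self, cat: str, words: list[str]) -> int:
        start = len(self.tokens)
        self.tokens.extend(words)
        if len(words) == 1:
            self.tags.append("B" + cat)
        else:
            self.tags.append("B" + cat)
            self.tags.extend("I" + cat for _ in words[1:-1])
            self.tags.append("E" + cat)
        self.ents.append((cat, start, len(self.tokens), " ".join(words)))
        return len(self.ents) - 1

    def relate(self, i: int, j: int) -> None:
        self.pos_pairs.append((i, j))


def _surf(words: list[str]) -> str:
    return " ".join(words)


class _ParagraphBuilder:
    def __init__(self, vocab: dict, cfg: GeneratorConfig, rng: random.Random,
                 paragraph_id: str):
        self.vocab = vocab
        self.cfg = cfg
        self.rng = rng
        self.pid = paragraph_id

    # -- sentence templates ------------------------------------------

    def prep_sentence(self, subject: list[str], reagent: dict,
                      amount: list[str], distract: bool) -> _Sentence:
        s = _Sentence()
        e = s.entity("E", subject)
        s.words("was", "prepared", "with")
        c = s.entity("C", reagent["name"])
        s.words("(")
        d = s.entity("D", amount)
        s.words(")")
        if distract:
            s.words("and")
            s.entity("C", self.rng.choice(self.vocab["distractor_reagents"]))
        s.words(".")
        s.relate(e, c)
        s.relate(c, d)
        return s

    def step_sentence(self, subject: list[str] | None, step: dict,
                      reagent: list[str] | None,
                      value: list[str] | None) -> _Sentence:
        s = _Sentence()
        if subject is not None:
            e = s.entity("E", subject)
            s.words("was")
        else:
            e = None
            s.words("Thereafter", "it", "was")
        m = s.entity("M", [step["verb"]])
        s.step_ent = m
        if e is not None:
            s.relate(e, m)
        if reagent is not None:
            s.words("with")
            c = s.entity("C", reagent)
            s.relate(m, c)
        if value is not None:
            s.words("at" if value[-1] == "°C" else "for")
            d = s.entity("D", value)
            s.relate(m, d)
        s.words(".")
        return s

    def char_sentence(self, subject: list[str],
                      props: list[tuple[list[str], list[str]]],
                      distract: bool) -> _Sentence:
        s = _Sentence()
        e = s.entity("E", subject)
        s.words("exhibited")
        for k, (name, value) in enumerate(props):
            if k:
                s.words("and")
            r = s.entity("R", name)
            s.words("of")
            v = s.entity("V", value)
            s.relate(e, r)
            s.relate(r, v)
            s.relate(e, v)
        if distract:
            s.words("(", "vs")
            s.entity("V", self.rng.choice(self.vocab["distractor_values"]))
            s.words(")")
        s.words(".")
        return s

    # -- paragraph assembly ------------------------------------------

    def build(self) -> GoldBundle:
        rng, vocab, cfg = self.rng, self.vocab, self.cfg
        patterns = sorted(cfg.pattern_weights)
        weights = [cfg.pattern_weights[p] for p in patterns]
        pattern = rng.choices(patterns, weights=weights, k=1)[0]

        specifics = rng.sample(vocab["specific_materials"], k=2)
        product = specifics[0]
        specific2 = specifics[1] if pattern in ("two_specific", "general_two") else None
        general = (rng.choice(vocab["general_materials"])
                   if pattern in ("general", "general_alias", "general_two")
                   else None)
        alias = (rng.choice(vocab["aliases"])
                 if pattern in ("alias", "general_alias") else None)

        # the product's recipe
        n_steps = rng.randint(cfg.min_steps, cfg.max_steps)
        start = rng.randint(0, len(vocab["steps"]) - n_steps)
        steps = vocab["steps"][start:start + n_steps]
        step_plan = []
        for i, step in enumerate(steps):
            reagent = (rng.choice(step["reagents"])
                       if step["reagents"] and rng.random() < 0.8 else None)
            value = (rng.choice(step["values"]) if rng.random() < 0.9 else None)
            step_plan.append({"step": step, "reagent": reagent, "value": value,
                              "subject": None})
        step_plan[0]["subject"] = "product"
        if alias is not None and n_steps >= 2:
            alias_idx = rng.randint(1, n_steps - 1)
            step_plan[alias_idx]["subject"] = "alias"
        for plan in step_plan[1:]:
            if plan["subject"] is None and rng.random() < 0.5:
                plan["subject"] = "product"

        prep_reagent = rng.choice(vocab["prep_reagents"])
        prep_amount = rng.choice(prep_reagent["amounts"])
        n_props = rng.randint(1, 2)
        props = [(p["name"], rng.choice(p["values"]))
                 for p in rng.sample(vocab["properties"], k=n_props)]

        sentences: list[tuple[str, _Sentence]] = []
        sentences.append(("product", self.prep_sentence(
            product, prep_reagent, prep_amount,
            rng.random() < cfg.distractor_rate)))
        for plan in step_plan:
            subject = {"product": product, "alias": alias, None: None}[plan["subject"]]
            sentences.append(("product", self.step_sentence(
                subject, plan["step"], plan["reagent"], plan["value"])))
        sentences.append(("product", self.char_sentence(
            product, props, rng.random() < cfg.distractor_rate)))

        # general material: its own preparation statement
        gen_conflict = False
        gen_reagent = gen_amount = None
        if general is not None:
            if rng.random() < 0.5 and len(prep_reagent["amounts"]) > 1:
                gen_reagent = prep_reagent
                others = [a for a in prep_reagent["amounts"] if a != prep_amount]
                gen_amount = rng.choice(others)
                gen_conflict = True
            else:
                choices = [r for r in vocab["prep_reagents"]
                           if r["name"] != prep_reagent["name"]]
                gen_reagent = rng.choice(choices)
                gen_amount = rng.choice(gen_reagent["amounts"])
            sentences_extra = ("general", self.prep_sentence(
                general, gen_reagent, gen_amount, False))
        spec2_props = None
        extra: list[tuple[str, _Sentence]] = []
        if general is not None:
            extra.append(sentences_extra)
        if specific2 is not None:
            spec2_props = [(p["name"], rng.choice(p["values"]))
                           for p in rng.sample(vocab["properties"], k=1)]
            extra.append(("specific2", self.char_sentence(
                specific2, spec2_props, rng.random() < cfg.distractor_rate)))

        for item in extra:
            if rng.random() < cfg.alternation_density and len(sentences) > 1:
                pos = rng.randint(1, len(sentences) - 1)
                sentences.insert(pos, item)
            else:
                sentences.append(item)

        # globalize tokens, tags, spans
        words: list[str] = []
        tags: list[str] = []
        bounds: list[tuple[int, int]] = []
        offsets: list[int] = []
        for _, sent in sentences:
            offsets.append(len(words))
            words.extend(sent.tokens)
            tags.extend(sent.tags)
            bounds.append((offsets[-1], len(words)))
        paragraph = AnnotatedParagraph(
            paragraph_id=self.pid,
            tokens=tokens_from_strings(words), tags=tags, sentences=bounds,
        )

        positives: set[tuple[tuple[int, int], tuple[int, int]]] = set()
        chain: list[tuple[int, int]] = []
        step_spans: list[tuple[int, int]] = []
        for (_, sent), off in zip(sentences, offsets):
            for i, j in sent.pos_pairs:
                a = (sent.ents[i][1] + off, sent.ents[i][2] + off)
                b = (sent.ents[j][1] + off, sent.ents[j][2] + off)
                positives.add((a, b))
            if sent.step_ent is not None:
                ent = sent.ents[sent.step_ent]
                step_spans.append((ent[1] + off, ent[2] + off))
        chain = step_spans  # product sentences keep narrative order
        for u, v in zip(chain, chain[1:]):
            positives.add((u, v))

        relations = build_candidates(paragraph, gold=positives)
        mm = [r for r in chain_steps(paragraph, gold_chain=chain)]
        relations.extend(mm)

        # paragraph-level labels
        names: dict[str, str] = {normalize_name(_surf(product)): "specific"}
        if alias is not None:
            names[normalize_name(_surf(alias))] = "alias"
        if general is not None:
            names[normalize_name(_surf(general))] = "general"
        if specific2 is not None:
            names[normalize_name(_surf(specific2))] = "specific2"
        pair_labels = []
        ordered = sorted(names)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1:]:
                ka, kb = names[a], names[b]
                if "general" in (ka, kb):
                    label = "A_INCLUDES_B" if ka == "general" else "B_INCLUDES_A"
                elif {ka, kb} == {"alias", "specific"}:
                    label = "IDENTICAL"
                else:
                    label = "UNRELATED"
                pair_labels.append(MaterialPairRecord(
                    paragraph_id=self.pid, material_a=a, material_b=b,
                    label=label))

        graphs, merged = self._gold_graphs(
            product, alias, general, specific2, step_plan, chain,
            prep_reagent, prep_amount, props, gen_reagent, gen_amount,
            gen_conflict, spec2_props)
        return GoldBundle(
            paragraph=paragraph, relations=relations,
            pair_labels=pair_labels, graphs=graphs, merged=merged,
            chain=chain,
        )

    # -- gold graphs from recipe metadata ----------------------------

    def _gold_graphs(self, product, alias, general, specific2, step_plan,
                     chain, prep_reagent, prep_amount, props,
                     gen_reagent, gen_amount, gen_conflict, spec2_props):
        def enode(words):
            return ("E", normalize_name(_surf(words)))

        def mknode(cat, words):
            return (cat, normalize_name(_surf(words)))

        def mnode(span):
            return ("M", self.pid, span[0], span[1])

        graphs: dict[str, MaterialStructureGraph] = {}

        def add_chain(g: MaterialStructureGraph, anchor_role: str) -> None:
            for plan, span in zip(step_plan, chain):
                nid = mnode(span)
                g.add_node(nid, plan["step"]["verb"])
            for u, v in zip(chain, chain[1:]):
                g.add_edge("MM", mnode(u), mnode(v))
            for plan, span in zip(step_plan, chain):
                if plan["reagent"] is not None:
                    cid = mknode("C", plan["reagent"])
                    g.add_node(cid, _surf(plan["reagent"]))
                    g.add_edge("MC", mnode(span), cid)
                if plan["value"] is not None:
                    did = mknode("D", plan["value"])
                    g.add_node(did, _surf(plan["value"]))
                    g.add_edge("MD", mnode(span), did)
            anchored = [span for plan, span in zip(step_plan, chain)
                        if plan["subject"] == anchor_role]
            if anchored:
                g.add_edge("EM", g.root, mnode(anchored[-1]))

        # product
        g = MaterialStructureGraph(root=enode(product))
        g.add_node(g.root, _surf(product))
        add_chain(g, "product")
        cid = mknode("C", prep_reagent["name"])
        g.add_node(cid, _surf(prep_reagent["name"]))
        g.add_edge("EC", g.root, cid)
        did = mknode("D", prep_amount)
        g.add_node(did, _surf(prep_amount))
        g.add_edge("CD", cid, did)
        for name, value in props:
            rid, vid = mknode("R", name), mknode("V", value)
            g.add_node(rid, _surf(name))
            g.add_node(vid, _surf(value))
            g.add_edge("ER", g.root, rid)
            g.add_edge("RV", rid, vid)
        graphs[g.root[1]] = g

        if alias is not None:
            ga = MaterialStructureGraph(root=enode(alias))
            ga.add_node(ga.root, _surf(alias))
            add_chain(ga, "alias")
            graphs[ga.root[1]] = ga
        if general is not None:
            gg = MaterialStructureGraph(root=enode(general))
            gg.add_node(gg.root, _surf(general))
            cid = mknode("C", gen_reagent["name"])
            gg.add_node(cid, _surf(gen_reagent["name"]))
            gg.add_edge("EC", gg.root, cid)
            did = mknode("D", gen_amount)
            gg.add_node(did, _surf(gen_amount))
            gg.add_edge("CD", cid, did)
            graphs[gg.root[1]] = gg
        if specific2 is not None:
            g2 = MaterialStructureGraph(root=enode(specific2))
            g2.add_node(g2.root, _surf(specific2))
            for name, value in spec2_props:
                rid, vid = mknode("R", name), mknode("V", value)
                g2.add_node(rid, _surf(name))
                g2.add_node(vid, _surf(value))
                g2.add_edge("ER", g2.root, rid)
                g2.add_edge("RV", rid, vid)
            graphs[g2.root[1]] = g2

        # merged paragraph graphs (IDENTICAL union, then general→specific)
        merged: dict[NodeId, MaterialStructureGraph] = {}
        prod_merged = graphs[enode(product)[1]].copy()
        if alias is not None:
            ga = graphs[enode(alias)[1]]
            for nid, disp in ga.nodes.items():
                if nid != ga.root:
                    prod_merged.add_node(nid, disp)
            for t, s, d in sorted(ga.edges):
                s2 = prod_merged.root if s == ga.root else s
                d2 = prod_merged.root if d == ga.root else d
                prod_merged.add_edge(t, s2, d2)
        spec2_merged = (graphs[enode(specific2)[1]].copy()
                        if specific2 is not None else None)
        if general is not None:
            gg = graphs[enode(general)[1]]
            for target in [t for t in (prod_merged, spec2_merged) if t is not None]:
                conflict = (target is prod_merged) and gen_conflict
                if not conflict:
                    cid = mknode("C", gen_reagent["name"])
                    did = mknode("D", gen_amount)
                    target.add_node(cid, _surf(gen_reagent["name"]))
                    target.add_node(did, _surf(gen_amount))
                    target.add_edge("EC", target.root, cid)
                    target.add_edge("CD", cid, did)
            merged[gg.root] = gg.copy()
        merged[prod_merged.root] = prod_merged
        if spec2_merged is not None:
            merged[spec2_merged.root] = spec2_merged
        return graphs, merged


def generate(config: GeneratorConfig | None = None) -> list[GoldBundle]:
    """Generate a seed-deterministic gold corpus."""
    config = config or GeneratorConfig()
    config.validate()
    vocab = load_vocab()
    rng = random.Random(config.seed)
    bundles = []
    for i in range(config.n_paragraphs):
        builder = _ParagraphBuilder(vocab, config, rng, f"p{i:04d}")
        bundles.append(builder.build())
    if config.label_noise > 0:
        bundles = corrupt_labels(bundles, config.label_noise,
                                 config.seed + 10_000)
    return bundles


def corrupt_labels(bundles: list[GoldBundle], rate: float,
                   seed: int = 0) -> list[GoldBundle]:
    """Flip each gold label independently with probability ``rate``.

    Binary relation labels toggle 1 ↔ None; paragraph-level labels move
    to a uniformly random different class.  The flip masks are recorded
    on each bundle (``flipped_relations`` holds instance keys,
    ``flipped_pairs`` material-name pairs).  Gold graphs are left
    untouched: they describe the noise-free truth.
    """
    if not (0 <= rate < 0.5):
        raise ValueError("rate must be in [0, 0.5)")
    from .para_gcn import PARA_LABELS

    rng = random.Random(seed)
    out = []
    for bundle in bundles:
        flipped_r = []
        new_relations = []
        for inst in bundle.relations:
            if rng.random() < rate:
                new_label = None if inst.label == 1 else 1
                new_relations.append(replace(inst, label=new_label))
                flipped_r.append(inst.key())
            else:
                new_relations.append(inst)
        flipped_p = []
        new_pairs = []
        for rec in bundle.pair_labels:
            if rng.random() < rate:
                others = [l for l in PARA_LABELS if l != rec.label]
                new_pairs.append(replace(rec, label=rng.choice(others)))
                flipped_p.append((rec.material_a, rec.material_b))
            else:
                new_pairs.append(rec)
        out.append(replace(
            bundle, relations=new_relations, pair_labels=new_pairs,
            flipped_relations=frozenset(flipped_r),
            flipped_pairs=frozenset(flipped_p),
        ))
    return out


__all__ = [
    "GeneratorConfig",
    "GoldBundle",
    "load_vocab",
    "generate",
    "corrupt_labels",
]
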