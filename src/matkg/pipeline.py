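"""End-to-end orchestration: annotations → pairs → predictions → graphs.

A pipeline run is a pure function of (inputs, config, seeds).  Each
learned stage can run in ``gold`` passthrough mode — substituting gold
labels for model predictions — which isolates downstream stages for
testing; ``train`` mode fits the stage's model on the training side of
the paragraph-level split and predicts on the validation side.  The run
manifest records seeds, per-stage counts and SHA-256 digests of the
outputs, so reruns with identical configuration produce identical
digests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from . import __version__
from .corpus import AnnotatedParagraph, split_corpus, write_conll
from .encoders import make_encoder
from .pairs import subsample_negatives, write_jsonl
from .para_gcn import (
    ParaGCNConfig, predict_material_pairs, train_para_re, write_pairs_jsonl,
)
from .sentence_re import SentenceREConfig, predict_pairs, train_sentence_re
from .structuring import (
    ParagraphGraph, assemble, export_document_json, link_paragraphs,
    merge_paragraph,
)
from .para_gcn import group_materials
from .synth import GeneratorConfig, generate


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def structure_paragraph(paragraph: AnnotatedParagraph, relations,
                        pair_labels) -> ParagraphGraph:
    """Assemble and merge all material graphs of one paragraph."""
    graphs = {name: assemble(name, relations)
              for name in group_materials(paragraph)}
    labels = [(r.material_a, r.material_b, r.label) for r in pair_labels]
    return merge_paragraph(paragraph.paragraph_id, graphs, labels)


def _digest(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()


def default_config() -> dict:
    return {
        "output_dir": "pipeline_out",
        "corpus": {"synthetic": {}},
        "encoder": {"type": "hash", "d": 64, "seed": 0},
        "split": {"ratio": [10, 1], "seed": 0},
        "sentence_re": {"mode": "gold"},
        "para_re": {"mode": "gold"},
        "negative_ratio": 3.0,
    }


def run_pipeline(config: dict) -> dict:
    """Execute the full pipeline; returns the run manifest.

    Stages: corpus → split → candidate pairs → sentence RE → paragraph
    RE → structuring → export.  Any stage failure aborts with the stage
    name and cause.
    """
    cfg = default_config()
    cfg.update(config or {})
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config_digest": _digest(cfg),
                      "stages": {}}

    # --- corpus -----------------------------------------------------
    try:
        corpus_cfg = cfg["corpus"]
        if "synthetic" in corpus_cfg:
            gen = GeneratorConfig(**corpus_cfg["synthetic"])
            bundles = generate(gen)
            manifest["stages"]["corpus"] = {
                "source": "synthetic", "seed": gen.seed,
                "n_paragraphs": len(bundles),
            }
        else:
            raise ValueError("corpus config must contain a 'synthetic' block")
    except Exception as exc:
        raise PipelineError("corpus", exc) from exc
    paragraphs = [b.paragraph for b in bundles]
    if not paragraphs:
        manifest["stages"]["summary"] = {"n_paragraphs": 0, "n_relations": 0,
                                         "n_material_graphs": 0}
        return manifest
    write_conll(paragraphs, out_dir / "corpus.conll")

    # --- split ------------------------------------------------------
    try:
        split = split_corpus(paragraphs, ratio=tuple(cfg["split"]["ratio"]),
                             seed=cfg["split"]["seed"])
        manifest["stages"]["split"] = {
            "seed": split.seed, "ratio": list(split.ratio),
            "n_train": len(split.train), "n_validation": len(split.validation),
        }
    except Exception as exc:
        raise PipelineError("split", exc) from exc
    by_id = {p.paragraph_id: p for p in paragraphs}
    train_ids, val_ids = set(split.train), set(split.validation)

    encoder = make_encoder(cfg["encoder"])

    # --- sentence-level relations ------------------------------------
    try:
        mode = cfg["sentence_re"]["mode"]
        if mode == "gold":
            labeled = {b.paragraph.paragraph_id: b.relations for b in bundles}
            re_report = None
        elif mode == "train":
            train_insts = [r for b in bundles
                           if b.paragraph.paragraph_id in train_ids
                           for r in b.relations]
            train_insts = subsample_negatives(
                train_insts, ratio=cfg["negative_ratio"],
                seed=cfg["split"]["seed"])
            val_insts = [r for b in bundles
                         if b.paragraph.paragraph_id in val_ids
                         for r in b.relations]
            re_cfg = SentenceREConfig(**cfg["sentence_re"].get("config", {}))
            model, re_report = train_sentence_re(
                train_insts, paragraphs, encoder, re_cfg,
                val_instances=val_insts)
            model.save(out_dir / "sentence_re.model.json")
            labeled = {}
            for b in bundles:
                labeled[b.paragraph.paragraph_id] = predict_pairs(
                    model, b.relations, paragraphs, encoder)
        else:
            raise ValueError(f"unknown sentence_re mode {mode!r}")
        n_rel = sum(len(v) for v in labeled.values())
        manifest["stages"]["sentence_re"] = {
            "mode": mode, "n_instances": n_rel,
            "validation_f1": re_report.f1 if re_report else None,
        }
        write_jsonl([r for rs in labeled.values() for r in rs],
                    out_dir / "relations.jsonl")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("sentence_re", exc) from exc

    # --- paragraph-level relations -----------------------------------
    try:
        mode = cfg["para_re"]["mode"]
        if mode == "gold":
            pair_labels = {b.paragraph.paragraph_id: b.pair_labels
                           for b in bundles}
            para_report = None
        elif mode == "train":
            train_pairs = [r for b in bundles
                           if b.paragraph.paragraph_id in train_ids
                           for r in b.pair_labels]
            val_pairs = [r for b in bundles
                         if b.paragraph.paragraph_id in val_ids
                         for r in b.pair_labels]
            para_cfg = ParaGCNConfig(**cfg["para_re"].get("config", {}))
            model, para_report = train_para_re(
                train_pairs, paragraphs, encoder, para_cfg,
                val_records=val_pairs)
            model.save(out_dir / "para_re.model.json")
            pair_labels = {}
            for b in bundles:
                pair_labels[b.paragraph.paragraph_id] = predict_material_pairs(
                    model, b.pair_labels, paragraphs, encoder)
        else:
            raise ValueError(f"unknown para_re mode {mode!r}")
        n_pairs = sum(len(v) for v in pair_labels.values())
        manifest["stages"]["para_re"] = {
            "mode": mode, "n_pairs": n_pairs,
            "validation_accuracy": para_report.accuracy if para_report else None,
        }
        write_pairs_jsonl([r for rs in pair_labels.values() for r in rs],
                          out_dir / "material_pairs.jsonl")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("para_re", exc) from exc

    # --- structuring + export ----------------------------------------
    try:
        from .structuring import StructuringError

        paragraph_graphs = []
        skipped = []
        for para in paragraphs:
            try:
                pg = structure_paragraph(
                    para, labeled[para.paragraph_id],
                    pair_labels[para.paragraph_id])
            except StructuringError as exc:
                # predicted relations can violate chain/label assumptions;
                # record and keep going rather than aborting the run
                skipped.append({"paragraph_id": para.paragraph_id,
                                "reason": str(exc)})
                pg = ParagraphGraph(paragraph_id=para.paragraph_id, graphs={})
            paragraph_graphs.append(pg)
        doc = link_paragraphs(paragraph_graphs)
        export_document_json(doc, out_dir / "document_graph.json")
        n_graphs = sum(len(pg.graphs) for pg in paragraph_graphs)
        manifest["stages"]["structuring"] = {
            "n_material_graphs": n_graphs,
            "n_cross_paragraph_links": len(doc.links),
            "n_skipped_paragraphs": len(skipped),
            "skipped": skipped,
        }
        manifest["stages"]["summary"] = {
            "n_paragraphs": len(paragraphs), "n_relations": n_rel,
            "n_material_graphs": n_graphs,
        }
        manifest["output_digests"] = {
            "document_graph": _digest([
                {str(root): sorted(map(str, g.edges))
                 for root, g in sorted(pg.graphs.items())}
                for pg in paragraph_graphs
            ]),
        }
    except Exception as exc:
        raise PipelineError("structuring", exc) from exc

    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


__all__ = ["PipelineError", "run_pipeline", "structure_paragraph",
           "default_config"]
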