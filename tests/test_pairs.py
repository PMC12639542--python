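"""Typed pair-candidate generation, policy table and the M-M chain."""

import itertools

from matkg.corpus import CATEGORIES
from matkg.pairs import (
    Policy, build_candidates, chain_steps, default_policy_table, pair_type,
    subsample_negatives,
)
from conftest import make_paragraph


class TestPolicyTable:
    def test_semantically_excluded_pairs(self):
        table = default_policy_table()
        for pt in ("MV", "RD", "CV"):
            assert table[pt] is Policy.EXCLUDE

    def test_material_material_delegated_to_paragraph_level(self):
        assert default_policy_table()["EE"] is Policy.EXCLUDE

    def test_covers_all_21_unordered_pairs_once(self):
        table = default_policy_table()
        assert len(table) == 21
        seen = set()
        for a, b in itertools.combinations_with_replacement(CATEGORIES, 2):
            pt = pair_type(a, b)
            assert pt == pair_type(b, a)
            assert pt in table
            seen.add(pt)
        assert len(seen) == 21

    def test_always_link_preset(self):
        table = default_policy_table(always_link_preset=True)
        for pt in ("ER", "EM", "RV"):
            assert table[pt] is Policy.ALWAYS_LINK
        assert table["EC"] is Policy.CLASSIFY


class TestBuildCandidates:
    def test_excluded_types_never_emitted(self, simple_paragraph):
        insts = build_candidates(simple_paragraph)
        assert all(default_policy_table()[i.pair_type] is not Policy.EXCLUDE
                   for i in insts)

    def test_mv_pair_absent(self):
        para = make_paragraph(
            "p", [["BG", "stirred", "350", "m2/g"]],
            [["BE", "BM", "BV", "EV"]])
        types = {i.pair_type for i in build_candidates(para)}
        assert types == {"EM", "EV"}  # MV excluded

    def test_single_mention_sentence_empty(self):
        para = make_paragraph("p", [["BG", "only"]], [["BE", "O"]])
        assert build_candidates(para) == []

    def test_matches_brute_force_double_loop(self, small_corpus):
        policy = default_policy_table()
        for bundle in small_corpus[:10]:
            para = bundle.paragraph
            got = {(i.mention_a.span, i.mention_b.span)
                   for i in build_candidates(para)}
            expected = set()
            mentions = para.get_mentions()
            for a, b in itertools.combinations(
                    sorted(mentions, key=lambda m: m.token_start), 2):
                same = any(s <= a.token_start and b.token_end <= e
                           for s, e in para.sentences)
                if same and policy[pair_type(a.category, b.category)] \
                        is not Policy.EXCLUDE:
                    expected.add((a.span, b.span))
            assert got == expected

    def test_candidates_never_cross_sentences(self, small_corpus):
        for bundle in small_corpus[:10]:
            para = bundle.paragraph
            for inst in build_candidates(para):
                s, e = para.sentences[inst.sentence_index]
                assert s <= inst.mention_a.token_start
                assert inst.mention_b.token_end <= e

    def test_gold_labels_applied(self, simple_paragraph):
        mentions = simple_paragraph.get_mentions()
        e = next(m for m in mentions if m.category == "E")
        c = next(m for m in mentions if m.category == "C")
        insts = build_candidates(simple_paragraph, gold={(e.span, c.span)})
        by_type = {i.pair_type: i.label for i in insts}
        assert by_type["EC"] == 1

    def test_count_bounded_by_pairwise_combinations(self, small_corpus):
        for bundle in small_corpus:
            para = bundle.paragraph
            bound = 0
            for s, e in para.sentences:
                k = sum(1 for m in para.get_mentions()
                        if s <= m.token_start and m.token_end <= e)
                bound += k * (k - 1) // 2
            assert len(build_candidates(para)) <= bound


class TestChainSteps:
    @staticmethod
    def _step_para():
        return make_paragraph(
            "p",
            [["BG", "stirred", "."], ["then", "aged", "."],
             ["then", "calcined", "."]],
            [["BE", "BM", "O"], ["O", "BM", "O"], ["O", "BM", "O"]])

    def test_sequential_gold_chain(self):
        para = self._step_para()
        spans = [m.span for m in para.get_mentions() if m.category == "M"]
        insts = chain_steps(para, gold_chain=spans)
        labels = {(i.mention_a.span, i.mention_b.span): i.label for i in insts}
        assert labels[(spans[0], spans[1])] == 1
        assert labels[(spans[1], spans[2])] == 1
        assert labels[(spans[0], spans[2])] is None

    def test_single_step_no_candidates(self, simple_paragraph):
        assert chain_steps(simple_paragraph, gold_chain=[]) == []

    def test_gold_chain_from_metadata_not_token_order(self):
        # narrate steps out of order: chain follows metadata
        para = self._step_para()
        spans = [m.span for m in para.get_mentions() if m.category == "M"]
        chain = [spans[1], spans[0], spans[2]]  # aged -> stirred -> calcined
        labels = {(i.mention_a.span, i.mention_b.span): i.label
                  for i in chain_steps(para, gold_chain=chain)}
        assert labels[(spans[0], spans[1])] == 1   # adjacent in chain
        assert labels[(spans[0], spans[2])] == 1   # stirred->calcined adjacent
        assert labels[(spans[1], spans[2])] is None

    def test_generated_chains_match_generator_metadata(self, small_corpus):
        for bundle in small_corpus[:10]:
            mm = [r for r in bundle.relations if r.pair_type == "MM"]
            adjacent = {frozenset((u, v)) for u, v in
                        zip(bundle.chain, bundle.chain[1:])}
            for inst in mm:
                expected = 1 if frozenset(
                    (inst.mention_a.span, inst.mention_b.span)) in adjacent \
                    else None
                assert inst.label == expected


class TestSubsample:
    def test_keeps_all_positives_caps_negatives(self, small_corpus):
        insts = [r for b in small_corpus for r in b.relations]
        out = subsample_negatives(insts, ratio=0.5, seed=0)
        n_pos = sum(1 for i in insts if i.label == 1)
        n_neg = sum(1 for i in insts if i.label != 1)
        assert sum(1 for i in out if i.label == 1) == n_pos
        assert sum(1 for i in out if i.label != 1) == \
            min(n_neg, round(0.5 * n_pos))

    def test_deterministic(self, small_corpus):
        insts = [r for b in small_corpus for r in b.relations]
        a = subsample_negatives(insts, ratio=0.5, seed=3)
        b = subsample_negatives(insts, ratio=0.5, seed=3)
        assert [i.key() for i in a] == [i.key() for i in b]
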