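"""Rule engine: assembly, merging, flattening, cross-paragraph linking."""

import random

import pytest

from matkg.corpus import EntityMention
from matkg.pairs import RelationInstance, pair_type
from matkg.structuring import (
    MaterialStructureGraph, StructuringError, assemble,
    assign_general_to_specific, flatten, link_paragraphs, merge_paragraph,
    merge_same, unflatten, ParagraphGraph,
)

_SPAN = [0]


def mention(cat, surf, span=None, pid="p"):
    if span is None:
        _SPAN[0] += 10
        span = (_SPAN[0], _SPAN[0] + 1)
    return EntityMention(category=cat, token_start=span[0], token_end=span[1],
                         paragraph_id=pid, surface=surf)


def rel(a, b, si=0, label=1, pid="p"):
    ma, mb = (a, b) if a.token_start < b.token_start else (b, a)
    return RelationInstance(
        paragraph_id=pid, sentence_index=si, mention_a=ma, mention_b=mb,
        pair_type=pair_type(a.category, b.category), label=label)


class TestAssemble:
    def test_erv_triple_forms_single_branch(self):
        e = mention("E", "MBG", (0, 1))
        r = mention("R", "SSA", (2, 3))
        v = mention("V", "350 m2/g", (4, 6))
        g = assemble("MBG", [rel(e, r), rel(r, v), rel(e, v)])
        assert ("ER", ("E", "mbg"), ("R", "ssa")) in g.edges
        assert ("RV", ("R", "ssa"), ("V", "350 m2/g")) in g.edges
        # EV absorbed into the chain: no direct E->V edge
        assert not any(t == "EV" for t, _, _ in g.edges)

    def test_ev_without_property_category_links_directly(self):
        e = mention("E", "MBG", (0, 1))
        v = mention("V", "5 nm", (3, 5))
        g = assemble("MBG", [rel(e, v)])
        assert ("EV", ("E", "mbg"), ("V", "5 nm")) in g.edges

    def test_empty_relations_root_only(self):
        g = assemble("MBG", [])
        assert g.root == ("E", "mbg")
        assert g.edges == set()

    def test_toy_chain_fixture(self):
        e = mention("E", "MBG", (0, 1))
        stir = mention("M", "stirred", (2, 3))
        calc = mention("M", "calcined", (10, 11))
        eth = mention("C", "ethanol", (4, 5))
        temp = mention("D", "600 °C", (12, 14))
        tep = mention("C", "TEP", (20, 21))
        relations = [
            rel(stir, calc, si=1), rel(stir, eth, si=1),
            rel(calc, temp, si=2), rel(e, calc, si=2), rel(e, tep, si=3),
        ]
        g = assemble("MBG", relations)
        stir_id, calc_id = ("M", "p", 2, 3), ("M", "p", 10, 11)
        assert g.edges == {
            ("MM", stir_id, calc_id),
            ("MC", stir_id, ("C", "ethanol")),
            ("MD", calc_id, ("D", "600 °c")),
            ("EM", ("E", "mbg"), calc_id),
            ("EC", ("E", "mbg"), ("C", "tep")),
        }

    def test_mc_attached_reagent_not_duplicated_under_root(self):
        # EC + MC + EM coexist: the C branch stays in the step list
        e = mention("E", "MBG", (0, 1))
        stir = mention("M", "stirred", (2, 3))
        eth = mention("C", "ethanol", (4, 5))
        g = assemble("MBG", [rel(e, stir, si=0), rel(stir, eth, si=0),
                             rel(e, eth, si=0)])
        assert ("MC", ("M", "p", 2, 3), ("C", "ethanol")) in g.edges
        assert ("EC", ("E", "mbg"), ("C", "ethanol")) not in g.edges

    def test_order_independent(self, small_corpus):
        rng = random.Random(0)
        for bundle in small_corpus[:5]:
            for name in bundle.graphs:
                shuffled = list(bundle.relations)
                rng.shuffle(shuffled)
                g1 = assemble(name, bundle.relations)
                g2 = assemble(name, shuffled)
                assert g1.edges == g2.edges and g1.root == g2.root

    def test_mm_cycle_rejected(self):
        e = mention("E", "MBG", (0, 1))
        m1 = mention("M", "stirred", (2, 3))
        m2 = mention("M", "aged", (4, 5))
        m3 = mention("M", "dried", (6, 7))
        relations = [rel(e, m1), rel(m1, m2), rel(m2, m3), rel(m1, m3)]
        with pytest.raises(StructuringError, match="cycle|branches"):
            assemble("MBG", relations)


def graph_with(root_name, branches):
    """Build a graph from (etype, src, dst) triples; root auto-added."""
    g = MaterialStructureGraph(root=("E", root_name))
    for t, s, d in branches:
        g.add_node(s, s[1])
        g.add_node(d, d[1])
        g.add_edge(t, s, d)
    return g


def random_graph(rng, root_name):
    g = MaterialStructureGraph(root=("E", root_name))
    for i in range(rng.randint(0, 5)):
        c = ("C", f"c{rng.randint(0, 4)}")
        g.add_node(c, c[1])
        g.add_edge("EC", g.root, c)
        if rng.random() < 0.5:
            d = ("D", f"d{rng.randint(0, 4)}")
            g.add_node(d, d[1])
            g.add_edge("CD", c, d)
    return g


class TestMergeSame:
    def test_idempotent(self):
        rng = random.Random(2)
        g = random_graph(rng, "mbg-58s glass")
        merged = merge_same(g, g.copy())
        assert merged.edges == g.edges

    def test_disjoint_branches_united(self):
        g1 = graph_with("mbg glass", [("EC", ("E", "mbg glass"), ("C", "tep"))])
        g2 = graph_with("sol", [("ER", ("E", "sol"), ("R", "ssa"))])
        merged = merge_same(g1, g2)
        assert merged.root == ("E", "mbg glass")  # longer surface wins
        assert ("EC", ("E", "mbg glass"), ("C", "tep")) in merged.edges
        assert ("ER", ("E", "mbg glass"), ("R", "ssa")) in merged.edges

    def test_commutative_union_oracle(self):
        rng = random.Random(3)
        for _ in range(30):
            g1 = random_graph(rng, "aaaa")
            g2 = random_graph(rng, "bbbbb")
            m12, m21 = merge_same(g1, g2), merge_same(g2, g1)
            assert m12.edges == m21.edges

            def rerooted(g, new_root):
                return {(t, new_root if s == g.root else s,
                         new_root if d == g.root else d)
                        for t, s, d in g.edges}
            oracle = rerooted(g1, m12.root) | rerooted(g2, m12.root)
            assert m12.edges == oracle


class TestAssignGeneralToSpecific:
    def test_conflicting_cd_branch_discarded(self):
        general = graph_with("glasses", [
            ("EC", ("E", "glasses"), ("C", "tep")),
            ("CD", ("C", "tep"), ("D", "5 ml")),
        ])
        specific = graph_with("mbg", [
            ("EC", ("E", "mbg"), ("C", "tep")),
            ("CD", ("C", "tep"), ("D", "4 ml")),
        ])
        out = assign_general_to_specific(general, specific)
        assert ("CD", ("C", "tep"), ("D", "5 ml")) not in out.edges
        assert ("CD", ("C", "tep"), ("D", "4 ml")) in out.edges

    def test_empty_general_is_noop(self):
        specific = graph_with("mbg", [("EC", ("E", "mbg"), ("C", "teos"))])
        out = assign_general_to_specific(
            MaterialStructureGraph(root=("E", "glasses")), specific)
        assert out.edges == specific.edges

    def test_non_conflicting_branch_copied_verbatim(self):
        general = graph_with("glasses", [
            ("EC", ("E", "glasses"), ("C", "citric acid")),
            ("CD", ("C", "citric acid"), ("D", "50 g")),
        ])
        specific = graph_with("mbg", [("EC", ("E", "mbg"), ("C", "teos"))])
        out = assign_general_to_specific(general, specific)
        assert ("EC", ("E", "mbg"), ("C", "citric acid")) in out.edges
        assert ("CD", ("C", "citric acid"), ("D", "50 g")) in out.edges
        assert ("EC", ("E", "mbg"), ("C", "teos")) in out.edges


class TestMergeParagraph:
    def test_same_chain_transitive_closure(self):
        names = ["mat aaa", "mat bb", "mat c"]
        graphs = {n: graph_with(n, [("EC", ("E", n), ("C", f"c{i}"))])
                  for i, n in enumerate(names)}
        labels = [("mat aaa", "mat bb", "IDENTICAL"),
                  ("mat bb", "mat c", "IDENTICAL")]
        pg = merge_paragraph("p", graphs, labels)
        assert len(pg.graphs) == 1
        (g,) = pg.graphs.values()
        # union-find oracle: all three branches under the longest root
        assert g.root == ("E", "mat aaa")
        assert {d for _, _, d in g.edges} == {("C", "c0"), ("C", "c1"),
                                              ("C", "c2")}

    def test_all_unrelated_unchanged(self):
        graphs = {n: graph_with(n, [("EC", ("E", n), ("C", "x"))])
                  for n in ["a", "b"]}
        pg = merge_paragraph("p", graphs, [("a", "b", "UNRELATED")])
        assert len(pg.graphs) == 2
        for g in pg.graphs.values():
            assert len(g.edges) == 1

    def test_same_plus_inclusion_fixture(self):
        product = graph_with("mbg-58s glass", [
            ("EC", ("E", "mbg-58s glass"), ("C", "tep")),
            ("CD", ("C", "tep"), ("D", "5 ml")),
        ])
        alias = graph_with("the sol", [
            ("ER", ("E", "the sol"), ("R", "ssa")),
        ])
        general = graph_with("bioactive glasses", [
            ("EC", ("E", "bioactive glasses"), ("C", "teos")),
        ])
        pg = merge_paragraph(
            "p",
            {"mbg-58s glass": product, "the sol": alias,
             "bioactive glasses": general},
            [("mbg-58s glass", "the sol", "IDENTICAL"),
             ("bioactive glasses", "mbg-58s glass", "A_INCLUDES_B")])
        merged = pg.graphs[("E", "mbg-58s glass")]
        assert merged.edges == {
            ("EC", ("E", "mbg-58s glass"), ("C", "tep")),
            ("CD", ("C", "tep"), ("D", "5 ml")),
            ("ER", ("E", "mbg-58s glass"), ("R", "ssa")),
            ("EC", ("E", "mbg-58s glass"), ("C", "teos")),
        }

    def test_contradictory_inclusions_rejected(self):
        graphs = {n: MaterialStructureGraph(root=("E", n)) for n in ["a", "b"]}
        labels = [("a", "b", "A_INCLUDES_B"), ("a", "b", "B_INCLUDES_A")]
        with pytest.raises(StructuringError, match="contradictory"):
            merge_paragraph("p", graphs, labels)


class TestFlatten:
    def test_single_root(self):
        g = MaterialStructureGraph(root=("E", "mbg"))
        records = flatten(g)
        assert len(records) == 1 and records[0]["parent"] is None

    def test_fixture_golden_order(self):
        g = graph_with("mbg", [
            ("EC", ("E", "mbg"), ("C", "tep")),
            ("CD", ("C", "tep"), ("D", "5 ml")),
            ("ER", ("E", "mbg"), ("R", "ssa")),
            ("RV", ("R", "ssa"), ("V", "350 m2/g")),
        ])
        got = [(r["edge_type"], r["node"]) for r in flatten(g)]
        assert got == [
            (None, ("E", "mbg")),
            ("EC", ("C", "tep")),
            ("CD", ("D", "5 ml")),
            ("ER", ("R", "ssa")),
            ("RV", ("V", "350 m2/g")),
        ]

    def test_random_dags_topologically_valid(self):
        rng = random.Random(4)
        for _ in range(30):
            g = random_graph(rng, "root")
            records = flatten(g)
            position = {tuple(r["node"]): i for i, r in enumerate(records)}
            # independent checker: every edge goes forward in the listing
            for t, s, d in g.edges:
                assert position[s] < position[d] or s == d

    def test_flatten_unflatten_identity(self, small_corpus):
        for bundle in small_corpus[:8]:
            for g in bundle.graphs.values():
                back = unflatten(flatten(g))
                assert back.root == g.root and back.edges == g.edges

    def test_cycle_rejected(self):
        g = MaterialStructureGraph(root=("E", "m"))
        g.add_node(("C", "x"), "x")
        g.add_edge("EC", g.root, ("C", "x"))
        g.add_edge("EC", ("C", "x"), g.root)
        with pytest.raises(StructuringError, match="cycl"):
            flatten(g)


class TestLinkParagraphs:
    @staticmethod
    def _pg(pid, *names):
        return ParagraphGraph(paragraph_id=pid, graphs={
            ("E", n): MaterialStructureGraph(root=("E", n)) for n in names})

    def test_same_name_linked_across_gap(self):
        doc = link_paragraphs([self._pg("p0", "mbg"), self._pg("p1", "other"),
                               self._pg("p2", "mbg")])
        assert doc.links == [(0, ("E", "mbg"), 2, ("E", "mbg"))]

    def test_no_shared_names_no_links(self):
        doc = link_paragraphs([self._pg("p0", "a"), self._pg("p1", "b")])
        assert doc.links == []

    def test_case_and_whitespace_variants_linked(self):
        from matkg.para_gcn import normalize_name
        assert normalize_name("MBG ") == normalize_name("mbg")
        doc = link_paragraphs([self._pg("p0", normalize_name("MBG ")),
                               self._pg("p1", normalize_name("mbg"))])
        assert len(doc.links) == 1
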