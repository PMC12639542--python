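"""Deterministic assembly of per-material structure graphs.

Positive sentence-level relations are compiled, material by material,
into a directed structure graph: an experimental-step chain (M nodes)
with condition (C) and value (D) attachments, reagent branches hanging
off the material root, and property branches (property category R with
its value V).  Paragraph-level labels then merge the per-material
graphs: coreferent materials (IDENTICAL) are unioned, and branches of a
general material are assigned to its specific materials unless they
conflict.  Graphs flatten losslessly to topologically ordered record
lists, and graphs of the same material name link across paragraphs.

Node identity: experimental steps are events, so M nodes are identified
by their mention span; every other category is identified by
``(category, normalized surface)``, with the longest observed surface
kept for display.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import networkx as nx

from .corpus import EntityMention
from .pairs import RelationInstance
from .para_gcn import PARA_LABELS, normalize_name

EDGE_TYPES = ("MM", "MC", "MD", "EC", "EM", "ER", "EV", "RV", "CD")

NodeId = tuple
Edge = tuple  # (edge_type, src NodeId, dst NodeId)


class StructuringError(ValueError):
    pass


def node_id(mention: EntityMention) -> NodeId:
    """Stable node identity: span-based for steps, surface-based otherwise."""
    if mention.category == "M":
        return ("M", mention.paragraph_id, mention.token_start, mention.token_end)
    return (mention.category, normalize_name(mention.surface))


@dataclass
class MaterialStructureGraph:
    """Directed structure graph rooted at one material entity."""

    root: NodeId
    nodes: dict[NodeId, str] = field(default_factory=dict)  # id -> display
    edges: set[Edge] = field(default_factory=set)
    provenance: dict[Edge, str] = field(default_factory=dict)

    def __post_init__(self):
        self.nodes.setdefault(self.root, self.root[1])

    @property
    def root_name(self) -> str:
        return self.root[1]

    def add_node(self, nid: NodeId, display: str) -> None:
        old = self.nodes.get(nid, "")
        if len(display) > len(old):
            self.nodes[nid] = display
        else:
            self.nodes.setdefault(nid, display)

    def add_edge(self, etype: str, src: NodeId, dst: NodeId,
                 rule: str = "") -> None:
        edge = (etype, src, dst)
        if edge not in self.edges:
            self.edges.add(edge)
            if rule:
                self.provenance[edge] = rule

    def children(self, nid: NodeId) -> list[tuple[str, NodeId]]:
        return sorted((t, d) for t, s, d in self.edges if s == nid)

    def descendants(self, nid: NodeId) -> set[Edge]:
        """All edges reachable downward from ``nid`` (excluding its in-edge)."""
        out: set[Edge] = set()
        stack = [nid]
        seen = {nid}
        while stack:
            cur = stack.pop()
            for edge in self.edges:
                if edge[1] == cur:
                    out.add(edge)
                    if edge[2] not in seen:
                        seen.add(edge[2])
                        stack.append(edge[2])
        return out

    def copy(self) -> "MaterialStructureGraph":
        return MaterialStructureGraph(
            root=self.root, nodes=dict(self.nodes),
            edges=set(self.edges), provenance=dict(self.provenance),
        )

    def same_structure(self, other: "MaterialStructureGraph") -> bool:
        return self.root == other.root and self.edges == other.edges

    # -- export ------------------------------------------------------

    @staticmethod
    def _id_str(nid: NodeId) -> str:
        return "|".join(str(x) for x in nid)

    def to_json(self) -> dict:
        return {
            "root": self._id_str(self.root),
            "nodes": [
                {"id": self._id_str(n), "category": n[0], "surface": disp}
                for n, disp in sorted(self.nodes.items())
            ],
            "edges": [
                {"type": t, "src": self._id_str(s), "dst": self._id_str(d),
                 "rule": self.provenance.get((t, s, d), "")}
                for t, s, d in sorted(self.edges)
            ],
        }

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for n, disp in self.nodes.items():
            g.add_node(self._id_str(n), category=n[0], surface=disp,
                       is_root=(n == self.root))
        for t, s, d in sorted(self.edges):
            g.add_edge(self._id_str(s), self._id_str(d), type=t)
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def _by_category(inst: RelationInstance, cat: str) -> EntityMention:
    if inst.mention_a.category == cat:
        return inst.mention_a
    if inst.mention_b.category == cat:
        return inst.mention_b
    raise StructuringError(f"no {cat} mention in {inst.pair_type} instance")


def _chain_order(mm_edges: set[frozenset], positions: dict[NodeId, int]) -> list[NodeId]:
    """Orient the undirected step path; start at the earlier endpoint.

    Raises on cycles or branching (the chain must be a simple path).
    Disconnected chain fragments are each oriented and concatenated in
    document order.
    """
    adj: dict[NodeId, set[NodeId]] = {}
    for e in mm_edges:
        u, v = tuple(e)
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    for n, nbrs in adj.items():
        if len(nbrs) > 2:
            raise StructuringError(f"step chain branches at {n}")
    ordered: list[NodeId] = []
    visited: set[NodeId] = set()
    starts = sorted((n for n, nbrs in adj.items() if len(nbrs) <= 1),
                    key=lambda n: positions[n])
    for start in starts:
        if start in visited:
            continue
        cur, prev = start, None
        component = []
        while cur is not None:
            component.append(cur)
            visited.add(cur)
            nxt = None
            for nbr in adj[cur]:
                if nbr != prev:
                    nxt = nbr
                    break
            prev, cur = cur, nxt
            if cur in visited and cur is not None:
                raise StructuringError(f"cycle in step chain at {cur}")
        ordered.extend(component)
    if len(visited) < len(adj):
        cyc = sorted(set(adj) - visited, key=lambda n: positions[n])
        raise StructuringError(f"cycle in step chain involving {cyc[0]}")
    return ordered


def assemble(material: str, relations: list[RelationInstance]) -> MaterialStructureGraph:
    """Build one material's structure graph from positive relations.

    Rules, applied strictly in order:

    1. link MM relations into the step chain and attach MC reagents;
    2. attach MD values to steps in the chain;
    3. attach remaining C entities to the material via EC (a C already
       placed under a step by MC stays there);
    4. anchor the chain to the material at the EM-linked step that is
       last in chain order;
    5. form E→R→V property branches when ER, EV and RV co-occur,
       otherwise connect the pairs directly.

    CD values attach beneath C nodes of this graph, and RV values
    beneath its R nodes, only when they come from the same sentence as
    the relation that introduced the C or R node — reagent and property
    surfaces recur across materials in a paragraph, and sentence scope
    keeps each material's values on its own branches.
    """
    key = normalize_name(material)
    positive = [r for r in relations if r.label == 1]
    g = MaterialStructureGraph(root=("E", key))

    def is_mine(m: EntityMention) -> bool:
        return m.category == "E" and normalize_name(m.surface) == key

    for r in positive:
        for m in (r.mention_a, r.mention_b):
            if is_mine(m):
                g.add_node(("E", key), m.surface)

    # Steps of this material: EM-linked steps expanded through MM links.
    em_steps: set[NodeId] = set()
    for r in positive:
        if r.pair_type == "EM" and any(is_mine(m) for m in (r.mention_a, r.mention_b)):
            em_steps.add(node_id(_by_category(r, "M")))
    mm_adj: dict[NodeId, set[NodeId]] = {}
    mm_info: dict[NodeId, EntityMention] = {}
    for r in positive:
        if r.pair_type == "MM":
            u, v = node_id(r.mention_a), node_id(r.mention_b)
            mm_adj.setdefault(u, set()).add(v)
            mm_adj.setdefault(v, set()).add(u)
            mm_info[u] = r.mention_a
            mm_info[v] = r.mention_b
    steps = set(em_steps)
    stack = list(em_steps)
    while stack:
        cur = stack.pop()
        for nbr in mm_adj.get(cur, ()):
            if nbr not in steps:
                steps.add(nbr)
                stack.append(nbr)

    # (1) chain MM + attach MC
    mm_edges = {frozenset((u, v)) for u in steps for v in mm_adj.get(u, ())
                if v in steps}
    positions = {n: n[2] for n in steps}
    chain = _chain_order(mm_edges, positions) if mm_edges else sorted(
        steps, key=lambda n: positions[n])
    for n in chain:
        mention = mm_info.get(n)
        g.add_node(n, mention.surface if mention else n[1])
    for u, v in zip(chain, chain[1:]):
        if frozenset((u, v)) in mm_edges:
            g.add_edge("MM", u, v, rule="rule1")
    attached_c: set[NodeId] = set()
    c_sentences: set[tuple[int, NodeId]] = set()
    for r in positive:
        if r.pair_type == "MC":
            m, c = _by_category(r, "M"), _by_category(r, "C")
            mid = node_id(m)
            if mid in steps:
                cid = node_id(c)
                g.add_node(mid, m.surface)
                g.add_node(cid, c.surface)
                g.add_edge("MC", mid, cid, rule="rule1")
                attached_c.add(cid)
                c_sentences.add((r.sentence_index, cid))

    # (2) MD values onto chain steps
    for r in positive:
        if r.pair_type == "MD":
            m, dv = _by_category(r, "M"), _by_category(r, "D")
            mid = node_id(m)
            if mid in steps:
                did = node_id(dv)
                g.add_node(did, dv.surface)
                g.add_edge("MD", mid, did, rule="rule2")

    # (3) remaining C entities via EC
    for r in positive:
        if r.pair_type == "EC" and any(is_mine(m) for m in (r.mention_a, r.mention_b)):
            c = _by_category(r, "C")
            cid = node_id(c)
            if cid not in attached_c:
                g.add_node(cid, c.surface)
                g.add_edge("EC", g.root, cid, rule="rule3")
            c_sentences.add((r.sentence_index, cid))

    # (4) anchor the chain at the last EM-linked step
    em_in_chain = [n for n in chain if n in em_steps]
    if em_in_chain:
        g.add_edge("EM", g.root, em_in_chain[-1], rule="rule4")

    # CD attachments beneath this material's C nodes (sentence-scoped)
    for r in positive:
        if r.pair_type == "CD":
            c, dv = _by_category(r, "C"), _by_category(r, "D")
            cid = node_id(c)
            if (r.sentence_index, cid) in c_sentences:
                did = node_id(dv)
                g.add_node(did, dv.surface)
                g.add_edge("CD", cid, did, rule="rule2")

    # (5) property branches
    er_targets: set[NodeId] = set()
    r_sentences: set[tuple[int, NodeId]] = set()
    rv_pairs: set[tuple[int, NodeId, NodeId]] = set()
    ev_targets: set[NodeId] = set()
    surfaces: dict[NodeId, str] = {}
    for r in positive:
        if r.pair_type == "ER" and any(is_mine(m) for m in (r.mention_a, r.mention_b)):
            rm = _by_category(r, "R")
            er_targets.add(node_id(rm))
            r_sentences.add((r.sentence_index, node_id(rm)))
            surfaces[node_id(rm)] = rm.surface
        elif r.pair_type == "RV":
            rm, vm = _by_category(r, "R"), _by_category(r, "V")
            rv_pairs.add((r.sentence_index, node_id(rm), node_id(vm)))
            surfaces[node_id(rm)] = rm.surface
            surfaces[node_id(vm)] = vm.surface
        elif r.pair_type == "EV" and any(is_mine(m) for m in (r.mention_a, r.mention_b)):
            vm = _by_category(r, "V")
            ev_targets.add(node_id(vm))
            surfaces[node_id(vm)] = vm.surface
    for rid in sorted(er_targets):
        g.add_node(rid, surfaces[rid])
        g.add_edge("ER", g.root, rid, rule="rule5")
    consumed_v: set[NodeId] = set()
    for si, rid, vid in sorted(rv_pairs):
        if (si, rid) in r_sentences:
            g.add_node(vid, surfaces[vid])
            g.add_edge("RV", rid, vid, rule="rule5")
            if vid in ev_targets:
                consumed_v.add(vid)
    for vid in sorted(ev_targets - consumed_v):
        g.add_node(vid, surfaces[vid])
        g.add_edge("EV", g.root, vid, rule="rule5")
    return g


def merge_same(g1: MaterialStructureGraph,
               g2: MaterialStructureGraph) -> MaterialStructureGraph:
    """Union two coreferent materials' graphs under one canonical root.

    The canonical root keeps the longest surface form (ties broken
    lexicographically for determinism); branches of both graphs are
    copied and duplicate edges collapse.
    """
    d1, d2 = g1.nodes[g1.root], g2.nodes[g2.root]
    if (len(d1), d1) >= (len(d2), d2):
        primary, secondary = g1, g2
    else:
        primary, secondary = g2, g1
    out = primary.copy()

    def reroot(nid: NodeId) -> NodeId:
        return out.root if nid == secondary.root else nid

    for nid, disp in secondary.nodes.items():
        if nid != secondary.root:
            out.add_node(nid, disp)
    for t, s, d in sorted(secondary.edges):
        out.add_edge(t, reroot(s), reroot(d),
                     rule=secondary.provenance.get((t, s, d), ""))
    return out


def assign_general_to_specific(
    general: MaterialStructureGraph, specific: MaterialStructureGraph
) -> MaterialStructureGraph:
    """Copy the general material's branches into the specific one.

    A branch is a root edge plus everything reachable beneath it.  If
    the specific graph already holds a branch with the same anchor
    (same edge type and target, e.g. the same EC reagent) but different
    contents beneath it (e.g. a different CD value), the whole branch is
    discarded; the specific graph is never overwritten.
    """
    out = specific.copy()
    for t, s, d in sorted(general.edges):
        if s != general.root:
            continue
        branch = {(t, s, d)} | general.descendants(d)
        anchor_in_specific = (t, out.root, d) in out.edges
        if anchor_in_specific:
            spec_branch = {(t, out.root, d)} | out.descendants(d)
            gen_rerooted = {
                (bt, out.root if bs == general.root else bs, bd)
                for bt, bs, bd in branch
            }
            if spec_branch != gen_rerooted:
                continue  # conflicting branch: discard whole
        for bt, bs, bd in sorted(branch):
            bs2 = out.root if bs == general.root else bs
            for nid in (bs2, bd):
                if nid not in out.nodes:
                    out.add_node(nid, general.nodes.get(nid, str(nid[-1])))
            out.add_edge(bt, bs2, bd,
                         rule=general.provenance.get((bt, bs, bd), "assigned"))
    return out


@dataclass
class ParagraphGraph:
    """Merged per-paragraph material graphs, keyed by canonical root."""

    paragraph_id: str
    graphs: dict[NodeId, MaterialStructureGraph]

    def roots(self) -> list[NodeId]:
        return sorted(self.graphs)


def merge_paragraph(
    paragraph_id: str,
    graphs: dict[str, MaterialStructureGraph],
    para_labels: list[tuple[str, str, str]],
) -> ParagraphGraph:
    """Merge material graphs using paragraph-level pair labels.

    ``para_labels`` holds ``(material_a, material_b, label)`` with label
    one of the four paragraph-level classes.  Order of operations:
    IDENTICAL merges (transitively closed), then general-to-specific
    assignments, then a final IDENTICAL pass.  Contradictory inclusion
    labels raise; processing order is sorted for determinism.
    """
    by_name: dict[str, MaterialStructureGraph] = {
        normalize_name(k): v for k, v in graphs.items()
    }
    inclusions: dict[frozenset, tuple[str, str]] = {}
    same_pairs: list[tuple[str, str]] = []
    for a, b, label in para_labels:
        a, b = normalize_name(a), normalize_name(b)
        if label not in PARA_LABELS:
            raise StructuringError(f"unknown paragraph label {label!r}")
        if label == "IDENTICAL":
            same_pairs.append((a, b))
        elif label in ("A_INCLUDES_B", "B_INCLUDES_A"):
            general, specific = (a, b) if label == "A_INCLUDES_B" else (b, a)
            key = frozenset((a, b))
            if key in inclusions and inclusions[key] != (general, specific):
                raise StructuringError(
                    f"contradictory inclusion labels for pair ({a}, {b})"
                )
            inclusions[key] = (general, specific)

    # transitive closure of IDENTICAL via union-find
    parent = {name: name for name in by_name}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in same_pairs:
        if a in parent and b in parent:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[str]] = {}
    for name in sorted(by_name):
        groups.setdefault(find(name), []).append(name)
    merged: dict[str, MaterialStructureGraph] = {}
    rep_of: dict[str, str] = {}
    for rep, members in sorted(groups.items()):
        g = by_name[members[0]]
        for other in members[1:]:
            g = merge_same(g, by_name[other])
        for m in members:
            rep_of[m] = rep
        merged[rep] = g

    # general -> specific assignment on the merged graphs
    for key in sorted(inclusions, key=sorted):
        general, specific = inclusions[key]
        if general not in rep_of or specific not in rep_of:
            continue
        rg, rs = rep_of[general], rep_of[specific]
        if rg == rs:
            continue
        merged[rs] = assign_general_to_specific(merged[rg], merged[rs])

    # final IDENTICAL pass (idempotent after transitive closure)
    final: dict[NodeId, MaterialStructureGraph] = {}
    for rep in sorted(merged):
        g = merged[rep]
        final[g.root] = g
    return ParagraphGraph(paragraph_id=paragraph_id, graphs=final)


def flatten(graph: MaterialStructureGraph) -> list[dict]:
    """Stretch the graph into a topologically ordered record list.

    The first record is the root; each following record is one edge,
    ordered by the topological rank of its target (ties broken by edge
    type then node id).  The listing is lossless: :func:`unflatten`
    reconstructs the graph.  Cyclic graphs raise.
    """
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from((s, d) for _, s, d in graph.edges)
    try:
        topo = list(nx.lexicographical_topological_sort(
            g, key=lambda n: str(n)))
    except nx.NetworkXUnfeasible as exc:
        raise StructuringError("cannot flatten a cyclic graph") from exc
    rank = {n: i for i, n in enumerate(topo)}
    records = [{
        "node": graph.root, "category": graph.root[0],
        "surface": graph.nodes[graph.root], "parent": None, "edge_type": None,
    }]
    for t, s, d in sorted(graph.edges,
                          key=lambda e: (rank[e[2]], e[0], str(e[2]))):
        records.append({
            "node": d, "category": d[0], "surface": graph.nodes[d],
            "parent": s, "edge_type": t,
        })
    return records


def unflatten(records: list[dict]) -> MaterialStructureGraph:
    """Rebuild a structure graph from :func:`flatten` output."""
    root_rec = records[0]
    g = MaterialStructureGraph(root=tuple(root_rec["node"]))
    g.nodes[g.root] = root_rec["surface"]
    for rec in records[1:]:
        nid = tuple(rec["node"])
        g.add_node(nid, rec["surface"])
        g.add_edge(rec["edge_type"], tuple(rec["parent"]), nid)
    return g


def write_flat_csv(records: list[dict], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node", "category", "surface", "parent", "edge_type"])
        for rec in records:
            writer.writerow([
                MaterialStructureGraph._id_str(rec["node"]),
                rec["category"], rec["surface"],
                MaterialStructureGraph._id_str(rec["parent"]) if rec["parent"] else "",
                rec["edge_type"] or "",
            ])


@dataclass
class DocumentGraph:
    """Paragraph graphs in document order plus cross-paragraph links."""

    paragraphs: list[ParagraphGraph]
    links: list[tuple[int, NodeId, int, NodeId]]


def link_paragraphs(paragraph_graphs: list[ParagraphGraph]) -> DocumentGraph:
    """Link same-named material roots across paragraphs, in sequence.

    Each occurrence of a material name links to its next occurrence in
    a later paragraph (names compared after normalization).
    """
    last_seen: dict[str, tuple[int, NodeId]] = {}
    links: list[tuple[int, NodeId, int, NodeId]] = []
    for i, pg in enumerate(paragraph_graphs):
        for root in pg.roots():
            name = normalize_name(root[1])
            if name in last_seen:
                pi, proot = last_seen[name]
                links.append((pi, proot, i, root))
            last_seen[name] = (i, root)
    return DocumentGraph(paragraphs=paragraph_graphs, links=links)


def export_document_json(doc: DocumentGraph, path) -> None:
    obj = {
        "paragraphs": [
            {
                "paragraph_id": pg.paragraph_id,
                "materials": [g.to_json() for _, g in sorted(pg.graphs.items())],
            }
            for pg in doc.paragraphs
        ],
        "links": [
            {"from_paragraph": i, "from_root": MaterialStructureGraph._id_str(a),
             "to_paragraph": j, "to_root": MaterialStructureGraph._id_str(b)}
            for i, a, j, b in doc.links
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1)


__all__ = [
    "EDGE_TYPES",
    "StructuringError",
    "MaterialStructureGraph",
    "ParagraphGraph",
    "DocumentGraph",
    "node_id",
    "assemble",
    "merge_same",
    "assign_general_to_specific",
    "merge_paragraph",
    "flatten",
    "unflatten",
    "write_flat_csv",
    "link_paragraphs",
    "export_document_json",
]
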