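"""Single-sentence relation extraction over collapsed dependency graphs.

The parse of a simplified sentence is treated as an undirected labeled
graph (a rooted tree plus the collapsed-preposition / propagated-
conjunction edges from the enhanced-dependency column).  Three entities
are related when they share a *common node*: a node lying on all three
pairwise shortest paths, endpoints included.  This deliberately admits
the protein itself as the hub, which appositions like
"PSN1_HUMAN mutation (MUT0)" require.

Binary relations need a constraint beyond mere connectivity (otherwise
graph traversal would collapse into sentence co-occurrence): a pair is
related only if no *other* entity node of either endpoint's class lies
on a shortest path between them (interposition filter, a documented
heuristic).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .corpus_io import DISEASE, MUTATION, PROTEIN

SAME_SENTENCE = "SAME_SENTENCE"
ENTITY_LINK = "ENTITY_LINK"
TRIGGER_LINK = "TRIGGER_LINK"
COOCCUR_ABSTRACT = "COOCCUR_ABSTRACT"
COOCCUR_SENTENCE = "COOCCUR_SENTENCE"


class DependencyGraph:
    """Labeled dependency graph over one sentence's tokens.

    ``nodes`` maps token id (1-based) to the token form; ``entity_nodes``
    maps a placeholder token to the node id carrying it (bound after
    sentence simplification).
    """

    def __init__(self, key, forms: dict[int, str], lemmas: dict[int, str] | None = None):
        self.key = key
        self.nodes = dict(forms)
        self.lemmas = dict(lemmas or {})
        self.graph = nx.Graph()
        self.graph.add_nodes_from(self.nodes)
        self.entity_nodes: dict[str, int] = {}
        self.entity_class: dict[str, str] = {}

    def add_edge(self, governor: int, dependent: int, label: str) -> None:
        self.graph.add_edge(governor, dependent, label=label)

    def copy(self) -> "DependencyGraph":
        g = DependencyGraph(self.key, self.nodes, self.lemmas)
        g.graph = self.graph.copy()
        g.entity_nodes = dict(self.entity_nodes)
        g.entity_class = dict(self.entity_class)
        return g

    def bind_entities(self, placeholder_sentence) -> None:
        """Attach entity tokens from a simplified sentence to graph nodes
        by token-form equality (first occurrence wins)."""
        for sub in placeholder_sentence.substitutions:
            if sub.token in self.entity_nodes:
                continue
            for node_id in sorted(self.nodes):
                if self.nodes[node_id] == sub.token:
                    self.entity_nodes[sub.token] = node_id
                    self.entity_class[sub.token] = sub.mention.eclass
                    break

    def alias_entity(self, token: str, eclass: str, node_id: int) -> None:
        """Treat *node_id* (an anaphor / trigger node) as a stand-in for
        the entity *token* mentioned in another sentence."""
        if token not in self.entity_nodes:
            self.entity_nodes[token] = node_id
            self.entity_class[token] = eclass

    def tokens_by_class(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {PROTEIN: [], MUTATION: [], DISEASE: []}
        for token in sorted(self.entity_nodes):
            out[self.entity_class[token]].append(token)
        return out


@dataclass(frozen=True)
class Relation:
    """An extracted association between 2 or 3 entity placeholders.

    ``members`` is a set of (entity class, placeholder token) pairs;
    ternary relations hold exactly one protein, one mutation and one
    disease.  ``evidence`` records the sentence keys the relation was
    derived from, ``method`` the deriving mechanism.
    """

    members: frozenset[tuple[str, str]]
    method: str
    evidence: frozenset = frozenset()

    def __post_init__(self):
        classes = [c for c, _ in self.members]
        if len(self.members) == 3:
            if sorted(classes) != sorted([PROTEIN, MUTATION, DISEASE]):
                raise ValueError("ternary relations need one protein, one mutation, one disease")
        elif len(self.members) == 2:
            if classes[0] == classes[1]:
                raise ValueError("binary relations connect two distinct classes")
        else:
            raise ValueError("relations are binary or ternary")

    @property
    def arity(self) -> int:
        return len(self.members)

    def token_of(self, eclass: str) -> str | None:
        for c, t in self.members:
            if c == eclass:
                return t
        return None


def find_common_node(graph: DependencyGraph, node_a: int, node_b: int, node_c: int):
    """Node lying on all three pairwise undirected shortest paths
    (endpoints included), or None.  Ties resolve to the smallest id."""
    g = graph.graph
    for n in (node_a, node_b, node_c):
        if n not in g:
            raise KeyError(f"node {n} not in graph {graph.key}")
    da = nx.single_source_shortest_path_length(g, node_a)
    db = nx.single_source_shortest_path_length(g, node_b)
    dc = nx.single_source_shortest_path_length(g, node_c)
    if node_b not in da or node_c not in da or node_c not in db:
        return None  # disconnected components (malformed parse)
    dab, dac, dbc = da[node_b], da[node_c], db[node_c]
    candidates = [
        x for x in g.nodes
        if x in da and x in db and x in dc
        and da[x] + db[x] == dab
        and da[x] + dc[x] == dac
        and db[x] + dc[x] == dbc
    ]
    return min(candidates) if candidates else None


def _pair_blocked(graph: DependencyGraph, u: int, v: int,
                  blocked_nodes: set[int]) -> bool | None:
    """True if some node of *blocked_nodes* (other entities of either
    endpoint's class) lies on a shortest u-v path.  None: disconnected."""
    g = graph.graph
    du = nx.single_source_shortest_path_length(g, u)
    if v not in du:
        return None
    dv = nx.single_source_shortest_path_length(g, v)
    duv = du[v]
    for x in blocked_nodes:
        if x in (u, v):
            continue
        if x in du and x in dv and du[x] + dv[x] == duv:
            return True
    return False


def extract_sentence_relations(graph: DependencyGraph) -> list[Relation]:
    """All relations recoverable from one sentence's parse.

    Every (protein, mutation, disease) node triple sharing a common node
    yields a ternary relation; every cross-class pair whose shortest path
    has no interposed entity of either endpoint's class yields a binary
    relation.  Output is deduplicated on member sets.
    """
    by_class = graph.tokens_by_class()
    evidence = frozenset([graph.key])
    relations: list[Relation] = []
    seen: set[frozenset] = set()

    for p in by_class[PROTEIN]:
        for m in by_class[MUTATION]:
            for d in by_class[DISEASE]:
                hub = find_common_node(
                    graph,
                    graph.entity_nodes[p],
                    graph.entity_nodes[m],
                    graph.entity_nodes[d],
                )
                if hub is None:
                    continue
                members = frozenset([(PROTEIN, p), (MUTATION, m), (DISEASE, d)])
                if members not in seen:
                    seen.add(members)
                    relations.append(Relation(members, SAME_SENTENCE, evidence))

    class_nodes = {
        cls: {graph.entity_nodes[t] for t in tokens}
        for cls, tokens in by_class.items()
    }
    for ca, cb in ((PROTEIN, MUTATION), (PROTEIN, DISEASE), (MUTATION, DISEASE)):
        blocked_pool = class_nodes[ca] | class_nodes[cb]
        for ta in by_class[ca]:
            for tb in by_class[cb]:
                u, v = graph.entity_nodes[ta], graph.entity_nodes[tb]
                if u == v:
                    continue
                blocked = _pair_blocked(graph, u, v, blocked_pool)
                if blocked is not False:
                    continue
                members = frozenset([(ca, ta), (cb, tb)])
                if members not in seen:
                    seen.add(members)
                    relations.append(Relation(members, SAME_SENTENCE, evidence))
    return relations
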