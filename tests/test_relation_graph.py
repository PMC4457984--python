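"""Common-node traversal and single-sentence relation extraction."""

import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutrel import DISEASE, MUTATION, PROTEIN, DependencyGraph, find_common_node
from mutrel.association import extract_relations, prepare_document
from mutrel.relation_graph import extract_sentence_relations


def _graph(edges, n=None):
    nodes = {i for e in edges for i in e}
    n = n or max(nodes)
    g = DependencyGraph(("x", 0), {i: f"t{i}" for i in range(1, n + 1)})
    for a, b in edges:
        g.add_edge(a, b, "dep")
    return g


def brute_force_common(g: DependencyGraph, a, b, c):
    """Independent oracle: enumerate nodes; keep those lying on some
    shortest path for all three pairs (via path enumeration)."""
    def on_some_shortest_path(u, v, x):
        try:
            return any(x in p for p in nx.all_shortest_paths(g.graph, u, v))
        except nx.NetworkXNoPath:
            return None
    candidates = []
    for x in g.graph.nodes:
        oks = [on_some_shortest_path(u, v, x) for u, v in ((a, b), (a, c), (b, c))]
        if any(o is None for o in oks):
            return None
        if all(oks):
            candidates.append(x)
    return min(candidates) if candidates else None


def test_common_node_star():
    # A-X-B with C attached to X: X is the hub
    g = _graph([(1, 2), (2, 3), (2, 4)])
    assert find_common_node(g, 1, 3, 4) == 2


def test_common_node_protein_as_hub():
    # associated->PSN1_HUMAN, associated->D000544, PSN1_HUMAN->MUT0:
    # the protein node itself lies on all three pairwise paths
    g = _graph([(1, 2), (1, 3), (2, 4)])  # 1=associated 2=protein 3=disease 4=mutation
    assert find_common_node(g, 2, 4, 3) == 2


def test_common_node_disconnected_returns_none():
    g = _graph([(1, 2)], n=3)
    assert find_common_node(g, 1, 2, 3) is None


def test_common_node_unknown_node_raises():
    g = _graph([(1, 2)])
    with pytest.raises(KeyError):
        find_common_node(g, 1, 2, 99)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_common_node_matches_oracle_on_random_trees(seed):
    rng = random.Random(seed)
    n = rng.randint(3, 15)
    prufer = [rng.randrange(n) for _ in range(n - 2)] if n > 2 else []
    tree = nx.from_prufer_sequence(prufer) if n > 2 else nx.path_graph(n)
    g = DependencyGraph(("t", 0), {i + 1: f"t{i}" for i in range(n)})
    for a, b in tree.edges:
        g.add_edge(a + 1, b + 1, "dep")
    a, b, c = rng.sample(range(1, n + 1), 3)
    assert find_common_node(g, a, b, c) == brute_force_common(g, a, b, c)


def _bind(g, tokens):
    for token, (node, eclass) in tokens.items():
        g.entity_nodes[token] = node
        g.entity_class[token] = eclass
    return g


def test_apposition_sentence_yields_both_conjoined_ternaries(apposition_corpus):
    """Conjunction propagation makes both diseases reachable: one ternary
    relation per disease, on the shared protein/mutation pair."""
    doc = apposition_corpus.documents[0]
    prepared = prepare_document(doc, apposition_corpus.parses,
                                apposition_corpus.lexicons,
                                apposition_corpus.mentions_by_pmid[doc.pmid])
    relations = extract_relations(prepared, apposition_corpus.lexicons, "S3")
    ternary = {r.members for r in relations if r.arity == 3}
    assert ternary == {
        frozenset({(PROTEIN, "PSN1_HUMAN"), (MUTATION, "MUT0"), (DISEASE, "D000544")}),
        frozenset({(PROTEIN, "PSN1_HUMAN"), (MUTATION, "MUT0"), (DISEASE, "D004831")}),
    }


def test_ternary_implies_binary_projections(apposition_corpus):
    doc = apposition_corpus.documents[0]
    prepared = prepare_document(doc, apposition_corpus.parses,
                                apposition_corpus.lexicons,
                                apposition_corpus.mentions_by_pmid[doc.pmid])
    relations = extract_relations(prepared, apposition_corpus.lexicons, "S3")
    binaries = {r.members for r in relations if r.arity == 2}
    for r in (r for r in relations if r.arity == 3):
        members = sorted(r.members)
        for i in range(3):
            pair = frozenset(members[:i] + members[i + 1:])
            # each projection is itself derivable: the propagated
            # conjunction edge keeps the sibling disease off the path
            assert pair in binaries


def test_interposed_entity_blocks_binary_pair():
    # P - M1 - M2 chain: the path P..M2 passes through M1 (same class as
    # M2), so only the P-M1 pair is extracted
    g = _graph([(1, 2), (2, 3)])
    _bind(g, {"P1": (1, PROTEIN), "MUT0": (2, MUTATION), "MUT1": (3, MUTATION)})
    pairs = {r.members for r in extract_sentence_relations(g) if r.arity == 2}
    assert frozenset({(PROTEIN, "P1"), (MUTATION, "MUT0")}) in pairs
    assert frozenset({(PROTEIN, "P1"), (MUTATION, "MUT1")}) not in pairs


def test_collapsed_edge_unblocks_conjoined_mutation():
    # adding the propagated-conjunction edge restores the blocked pair
    g = _graph([(1, 2), (2, 3), (1, 3)])
    _bind(g, {"P1": (1, PROTEIN), "MUT0": (2, MUTATION), "MUT1": (3, MUTATION)})
    pairs = {r.members for r in extract_sentence_relations(g) if r.arity == 2}
    assert frozenset({(PROTEIN, "P1"), (MUTATION, "MUT1")}) in pairs


def test_single_entity_sentence_yields_no_relations():
    g = _graph([(1, 2)])
    _bind(g, {"P1": (1, PROTEIN)})
    assert extract_sentence_relations(g) == []
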