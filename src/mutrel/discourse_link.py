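"""Cross-sentence linking of dependency graphs.

Two mechanisms extend single-sentence extraction across the discourse:

* **entity identity** — graphs that share a placeholder token are merged
  transitively; a protein–disease relation in one sentence composes with
  a protein–mutation (or mutation–disease) relation in another through
  the shared entity, yielding a ternary relation;
* **trigger words / anaphora** — nouns like "mutation", "variant",
  "patient" are treated as anaphoric references to an entity of their
  class in the nearest preceding sentence (falling back to the nearest
  following one).  The trigger node is aliased to that entity, after
  which relation extraction and composition proceed as for identity
  links.

Linking only ever adds relations: per-document tuple sets are monotone
across the sentence-level, identity-linked and trigger-linked variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from .corpus_io import LexiconSet
from .relation_graph import (
    DISEASE, ENTITY_LINK, MUTATION, PROTEIN, TRIGGER_LINK,
    DependencyGraph, Relation, extract_sentence_relations,
)

log = logging.getLogger(__name__)

IDENTITY = "IDENTITY"
TRIGGER = "TRIGGER"


@dataclass
class LinkedGraph:
    """A set of sentence graphs connected by identity/trigger links."""

    keys: list = field(default_factory=list)
    graphs: list[DependencyGraph] = field(default_factory=list)
    links: list[tuple] = field(default_factory=list)  # (key_i, node_i, key_j, node_j, type)

    def tokens(self) -> set[str]:
        return {t for g in self.graphs for t in g.entity_nodes}


def _merge_components(graphs: list[DependencyGraph], link_type: str) -> list[LinkedGraph]:
    """Union-find over graphs sharing placeholder tokens."""
    parent = list(range(len(graphs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    token_owner: dict[str, int] = {}
    links: list[tuple] = []
    for i, g in enumerate(graphs):
        for token, node in sorted(g.entity_nodes.items()):
            if token in token_owner:
                j = token_owner[token]
                gj = graphs[j]
                links.append((gj.key, gj.entity_nodes[token], g.key, node, link_type))
                parent[find(i)] = find(j)
            else:
                token_owner[token] = i

    components: dict[int, LinkedGraph] = {}
    for i, g in enumerate(graphs):
        root = find(i)
        lg = components.setdefault(root, LinkedGraph())
        lg.keys.append(g.key)
        lg.graphs.append(g)
    for link in links:
        for lg in components.values():
            if link[0] in lg.keys:
                lg.links.append(link)
                break
    return [components[k] for k in sorted(components)]


def _compose(linked: list[LinkedGraph], relations: list[Relation],
             method: str) -> list[Relation]:
    """Ternary relations from pairs of binary relations in different
    sentences of one linked component that share an entity."""
    known = {r.members for r in relations}
    derived: list[Relation] = []
    for lg in linked:
        keyset = set(lg.keys)
        binaries = [r for r in relations
                    if r.arity == 2 and r.evidence and set(r.evidence) <= keyset]
        for r1, r2 in combinations(binaries, 2):
            if r1.evidence == r2.evidence:
                continue  # same sentence: the common-node rule owns that case
            shared = r1.members & r2.members
            if not shared:
                continue
            union = r1.members | r2.members
            classes = sorted(c for c, _ in union)
            if len(union) != 3 or classes != sorted([PROTEIN, MUTATION, DISEASE]):
                continue
            if union in known:
                continue
            known.add(union)
            derived.append(Relation(union, method, r1.evidence | r2.evidence))
    return derived


def link_by_entity(graphs: list[DependencyGraph],
                   relations: list[Relation]) -> tuple[list[LinkedGraph], list[Relation]]:
    """Merge graphs sharing placeholder tokens; compose ternary relations
    across sentences through the shared entities.  Sentence-level
    relations are retained; the returned list only holds the new ones."""
    linked = _merge_components(graphs, IDENTITY)
    derived = _compose(linked, relations, ENTITY_LINK)
    return linked, derived


def resolve_trigger(graphs: list[DependencyGraph], sentence_pos: int,
                    tclass: str) -> str | None:
    """Antecedent token for a trigger in sentence *sentence_pos*: nearest
    entity of the trigger's class in the nearest preceding sentence, else
    in the nearest following sentence."""
    order = list(range(sentence_pos - 1, -1, -1)) + \
        list(range(sentence_pos + 1, len(graphs)))
    for j in order:
        candidates = [(node, token) for token, node in graphs[j].entity_nodes.items()
                      if graphs[j].entity_class[token] == tclass]
        if candidates:
            return min(candidates)[1]  # nearest offset ~ smallest node id
    return None


def link_by_trigger(graphs: list[DependencyGraph], relations: list[Relation],
                    lexicons: LexiconSet) -> tuple[list[LinkedGraph], list[Relation]]:
    """Alias trigger/anaphor nodes to entities in neighbouring sentences
    and re-extract.

    Returns the linked components over the augmented graphs and the newly
    derived relations (tagged TRIGGER_LINK): sentence-level relations
    gained through an alias plus cross-sentence compositions.  The input
    *relations* list is never modified.
    """
    augmented = [g.copy() for g in graphs]
    trigger_links: list[tuple] = []
    for pos, g in enumerate(augmented):
        entity_node_ids = set(g.entity_nodes.values())
        for node_id in sorted(g.nodes):
            if node_id in entity_node_ids:
                continue
            word = g.lemmas.get(node_id) or g.nodes[node_id]
            tclass = lexicons.trigger_class(word)
            if tclass is None:
                continue
            antecedent = resolve_trigger(augmented, pos, tclass)
            if antecedent is None:
                log.debug("%s: trigger %r (node %d) unresolvable", g.key,
                          g.nodes[node_id], node_id)
                continue
            if antecedent in g.entity_nodes:
                continue  # one-to-one: token already anchored in this sentence
            g.alias_entity(antecedent, tclass, node_id)
            trigger_links.append((g.key, node_id, antecedent, TRIGGER))
            log.debug("%s: trigger %r -> %s", g.key, g.nodes[node_id], antecedent)

    known = {r.members for r in relations}
    new_sentence_rels: list[Relation] = []
    for g in augmented:
        for rel in extract_sentence_relations(g):
            if rel.members not in known:
                known.add(rel.members)
                new_sentence_rels.append(
                    Relation(rel.members, TRIGGER_LINK, rel.evidence))

    pool = relations + new_sentence_rels
    linked = _merge_components(augmented, TRIGGER)
    composed = _compose(linked, pool, TRIGGER_LINK)
    for lg in linked:
        for link in trigger_links:
            if link[0] in lg.keys:
                lg.links.append(link)
    return linked, new_sentence_rels + composed
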