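"""Co-occurrence baselines, system variants S1-S5, and assembly of final
normalized association tuples.

The five variants compared throughout the package:

* **S1** — abstract-level co-occurrence of protein x mutation x disease;
* **S2** — sentence-level co-occurrence;
* **S3** — single-sentence dependency-graph traversal;
* **S4** — S3 plus cross-sentence entity-identity linking;
* **S5** — S4 plus trigger-word / anaphora linking.

All variants share the same post-processing, so they are compared on an
identical tuple space: placeholders are retraced to their original
entities, residues mapped to 3-letter codes, text positions shifted by
the protein's signal-peptide length into database coordinates, and MeSH
disease ids mapped to OMIM (retaining every mapped id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

from .corpus_io import DISEASE, MUTATION, PROTEIN, Document, LexiconSet
from .discourse_link import link_by_entity, link_by_trigger
from .entity_layer import (EntityMention, MutationTriple, detect_abbreviations,
                           detect_mutations, merge_mentions, tag_dictionary)
from .relation_graph import (COOCCUR_ABSTRACT, COOCCUR_SENTENCE, DependencyGraph,
                             Relation, extract_sentence_relations)
from .simplify import DocumentState, PlaceholderSentence, substitute_entities

log = logging.getLogger(__name__)

SYSTEMS = ("S1", "S2", "S3", "S4", "S5")
ABSTRACT = "ABSTRACT"
SENTENCE = "SENTENCE"

RELATION_TYPES = ("PMD", "PM", "MD", "PD")


@dataclass(frozen=True)
class AssociationTuple:
    """A normalized association record.

    ``pos_text`` is the residue position as printed in the abstract,
    ``pos_norm`` the database-space position after adding the protein's
    signal-peptide length.  Binary records leave the fields of the absent
    entity as ``None`` / empty.
    """

    pmid: str
    uniprot_id: str | None
    wt: str | None
    pos_text: int | None
    pos_norm: int | None
    mut: str | None
    omim_ids: frozenset[str] = frozenset()
    method: str = ""
    evidence: tuple = ()

    @property
    def relation_type(self) -> str:
        has_p = self.uniprot_id is not None
        has_m = self.wt is not None
        has_d = bool(self.omim_ids)
        if has_p and has_m and has_d:
            return "PMD"
        if has_p and has_m:
            return "PM"
        if has_m and has_d:
            return "MD"
        if has_p and has_d:
            return "PD"
        raise ValueError("tuple covers fewer than two entity classes")

    def key(self) -> tuple:
        """Dedup key in database space, so the same biological variant
        reported with or without the signal offset collapses."""
        return (self.pmid, self.uniprot_id, self.wt, self.pos_norm,
                self.mut, self.omim_ids)


# ---------------------------------------------------------------------------
# elementary post-processing operations

def adjust_position(pos_text: int, signal_len: int) -> int:
    """Database-space residue position: text position plus the length of
    the signal-peptide region (0 when unknown/absent)."""
    if pos_text < 1:
        raise ValueError("text positions are 1-based")
    if signal_len < 0:
        raise ValueError("signal-peptide length must be non-negative")
    return pos_text + signal_len


def map_mesh_to_omim(mesh_id: str, lexicons: LexiconSet) -> frozenset[str]:
    """All OMIM ids mapped from a MeSH id; when several are mapped, all
    are retained.  Unmapped -> empty set (the tuple is dropped later)."""
    return lexicons.omim_for_mesh(mesh_id)


# ---------------------------------------------------------------------------
# co-occurrence baselines

def cooccur(mentions: list[EntityMention], level: str) -> list[Relation]:
    """Cartesian-product relations over normalized placeholder tokens.

    ABSTRACT pairs/triples any distinct tokens in the document; SENTENCE
    restricts the product to single sentences.  Mentions must already
    carry their placeholder tokens.
    """
    if level not in (ABSTRACT, SENTENCE):
        raise ValueError(f"level must be ABSTRACT or SENTENCE, got {level!r}")
    method = COOCCUR_ABSTRACT if level == ABSTRACT else COOCCUR_SENTENCE

    def scope_groups():
        if level == ABSTRACT:
            yield mentions
        else:
            indices = sorted({m.sentence_index for m in mentions})
            for i in indices:
                yield [m for m in mentions if m.sentence_index == i]

    relations: list[Relation] = []
    seen: set[frozenset] = set()
    for group in scope_groups():
        by_class: dict[str, dict[str, set]] = {PROTEIN: {}, MUTATION: {}, DISEASE: {}}
        for m in group:
            if m.token is None:
                continue
            by_class[m.eclass].setdefault(m.token, set()).add(
                (m.pmid, m.sentence_index))
        evid = {cls: toks for cls, toks in by_class.items()}
        for p, m_, d in product(sorted(evid[PROTEIN]), sorted(evid[MUTATION]),
                                sorted(evid[DISEASE])):
            members = frozenset([(PROTEIN, p), (MUTATION, m_), (DISEASE, d)])
            if members not in seen:
                seen.add(members)
                ev = frozenset(evid[PROTEIN][p] | evid[MUTATION][m_] | evid[DISEASE][d])
                relations.append(Relation(members, method, ev))
        for ca, cb in ((PROTEIN, MUTATION), (PROTEIN, DISEASE), (MUTATION, DISEASE)):
            for ta, tb in product(sorted(evid[ca]), sorted(evid[cb])):
                members = frozenset([(ca, ta), (cb, tb)])
                if members not in seen:
                    seen.add(members)
                    ev = frozenset(evid[ca][ta] | evid[cb][tb])
                    relations.append(Relation(members, method, ev))
    return relations


# ---------------------------------------------------------------------------
# tuple assembly

def _resolve_protein(token: str | None) -> str | None:
    if token is None or token.startswith("PROT"):
        return None  # unnormalized protein: cannot be benchmarked
    return token


def _resolve_mutation(token: str | None, doc_state: DocumentState) -> MutationTriple | None:
    if token is None:
        return None
    triple = doc_state.triple_for_token(token)
    if triple is None:
        raise ValueError(f"dangling mutation placeholder {token!r}")
    return triple


def _resolve_disease(token: str | None, lexicons: LexiconSet) -> frozenset[str]:
    if token is None or token.startswith("DIS"):
        return frozenset()
    return map_mesh_to_omim(token, lexicons)


def assemble_tuples(relations: list[Relation], lexicons: LexiconSet, pmid: str,
                    doc_state: DocumentState,
                    include_binary: bool = False) -> list[AssociationTuple]:
    """Turn relations over placeholders into normalized tuples.

    Ternary relations with an unnormalized protein (``PROTk``) or an
    unmapped disease are dropped (logged).  Output is deduplicated on the
    database-space key.  With ``include_binary`` the binary relations are
    assembled too (used for the PM/MD/PD evaluations).
    """
    out: list[AssociationTuple] = []
    seen: set[tuple] = set()
    for rel in relations:
        if rel.arity == 2 and not include_binary:
            continue
        p_tok = rel.token_of(PROTEIN)
        m_tok = rel.token_of(MUTATION)
        d_tok = rel.token_of(DISEASE)
        uniprot = _resolve_protein(p_tok)
        triple = _resolve_mutation(m_tok, doc_state)
        omims = _resolve_disease(d_tok, lexicons)

        has_p = p_tok is not None
        has_m = m_tok is not None
        has_d = d_tok is not None
        if has_p and uniprot is None:
            log.debug("pmid %s: dropping relation with unnormalized protein %s", pmid, p_tok)
            continue
        if has_d and not omims:
            log.debug("pmid %s: dropping relation with unmapped disease %s", pmid, d_tok)
            continue

        signal = lexicons.signal_lengths.get(uniprot, 0) if uniprot else 0
        tup = AssociationTuple(
            pmid=pmid,
            uniprot_id=uniprot,
            wt=triple.wt if triple else None,
            pos_text=triple.pos if triple else None,
            pos_norm=adjust_position(triple.pos, signal) if triple else None,
            mut=triple.mut if triple else None,
            omim_ids=omims if has_d else frozenset(),
            method=rel.method,
            evidence=tuple(sorted(rel.evidence)),
        )
        k = (tup.relation_type,) + tup.key()
        if k not in seen:
            seen.add(k)
            out.append(tup)
    return out


# ---------------------------------------------------------------------------
# document preparation and variant orchestration

@dataclass
class ProcessedDocument:
    document: Document
    mentions: list[EntityMention]
    placeholder_sentences: list[PlaceholderSentence]
    doc_state: DocumentState
    graphs: list[DependencyGraph]


def prepare_document(doc: Document, parses: dict, lexicons: LexiconSet,
                     mentions: list[EntityMention] | None = None,
                     extended_patterns: bool = False) -> ProcessedDocument:
    """Run term identification, abbreviation expansion, merging,
    placeholder substitution and graph binding for one abstract.

    Supplied *mentions* (e.g. PubTator annotations) are merged with the
    package's own pattern and dictionary annotators.  Sentences without a
    parse contribute to the co-occurrence baselines only (logged).
    """
    pools: list[list[EntityMention]] = []
    if mentions:
        pools.append(list(mentions))
    own: list[EntityMention] = []
    for sent in doc.sentences:
        own.extend(detect_mutations(sent, pmid=doc.pmid, extended=extended_patterns))
        own.extend(tag_dictionary(sent, lexicons, PROTEIN, pmid=doc.pmid))
        own.extend(tag_dictionary(sent, lexicons, DISEASE, pmid=doc.pmid))
    pools.append(own)
    combined = [m for pool in pools for m in pool]
    detect_abbreviations(doc, combined)
    merged = merge_mentions(combined)

    doc_state = DocumentState()
    placeholder_sentences = []
    graphs = []
    for sent in doc.sentences:
        ps = substitute_entities(sent, merged, doc_state, lexicons)
        placeholder_sentences.append(ps)
        parse = parses.get((doc.pmid, sent.index)) if parses else None
        if parse is None:
            if any(True for _ in ps.substitutions):
                log.info("pmid %s sentence %d has no parse; co-occurrence only",
                         doc.pmid, sent.index)
            continue
        g = parse.copy()
        g.bind_entities(ps)
        graphs.append(g)
    return ProcessedDocument(doc, merged, placeholder_sentences, doc_state, graphs)


def extract_relations(prepared: ProcessedDocument, lexicons: LexiconSet,
                      system: str) -> list[Relation]:
    """The relation set a given system variant derives for one document."""
    if system not in SYSTEMS:
        raise ValueError(f"unknown system {system!r}; expected one of {SYSTEMS}")
    if system == "S1":
        return cooccur(prepared.mentions, ABSTRACT)
    if system == "S2":
        return cooccur(prepared.mentions, SENTENCE)
    relations: list[Relation] = []
    for g in prepared.graphs:
        for rel in extract_sentence_relations(g):
            if rel.members not in {r.members for r in relations}:
                relations.append(rel)
    if system == "S3":
        return relations
    _, derived = link_by_entity(prepared.graphs, relations)
    relations = relations + derived
    if system == "S4":
        return relations
    _, trigger_derived = link_by_trigger(prepared.graphs, relations, lexicons)
    return relations + trigger_derived


def run_variant(doc: Document, parses: dict, lexicons: LexiconSet, system: str,
                mentions: list[EntityMention] | None = None,
                extended_patterns: bool = False) -> list[AssociationTuple]:
    """Full pipeline for one document and one system variant: returns the
    deduplicated ternary association tuples."""
    prepared = prepare_document(doc, parses, lexicons, mentions, extended_patterns)
    relations = extract_relations(prepared, lexicons, system)
    return assemble_tuples(relations, lexicons, doc.pmid, prepared.doc_state)


def run_variant_all_types(doc: Document, parses: dict, lexicons: LexiconSet,
                          system: str,
                          mentions: list[EntityMention] | None = None) -> dict[str, list[AssociationTuple]]:
    """Like :func:`run_variant` but also assembles binary (PM/MD/PD)
    records, keyed by relation type."""
    prepared = prepare_document(doc, parses, lexicons, mentions)
    relations = extract_relations(prepared, lexicons, system)
    tuples = assemble_tuples(relations, lexicons, doc.pmid, prepared.doc_state,
                             include_binary=True)
    out: dict[str, list[AssociationTuple]] = {t: [] for t in RELATION_TYPES}
    for tup in tuples:
        out[tup.relation_type].append(tup)
    return out
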