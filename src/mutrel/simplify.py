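"""Replace entity mentions with parser-safe placeholder tokens.

Before parsing, each sentence is "simplified": protein mentions become
their UniProt mnemonic (or a ``PROTk`` fallback when unnormalized),
disease mentions become their MeSH id, and mutation mentions become
``MUT`` plus a document-wide index assigned in order of first occurrence
— identical substitution triples reuse the same index.  The substitution
record is kept so every placeholder can be retraced to its original
span, and the original sentence can be reconstructed exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .corpus_io import DISEASE, MUTATION, PROTEIN, LexiconSet, Sentence
from .entity_layer import EntityMention, MutationTriple

_TOKEN_SAFE = re.compile(r"[^0-9A-Za-z_]")


def _sanitize(token: str) -> str:
    """Hyphens/periods inside ids become underscores so the token stays
    atomic for the parser."""
    return _TOKEN_SAFE.sub("_", token)


@dataclass
class DocumentState:
    """Document-scoped placeholder counters.

    Mutation indices are scoped to the abstract, not the sentence, so
    that a triple repeated across sentences maps to one token —
    cross-sentence identity linking depends on this.
    """

    mutation_index: dict[MutationTriple, int] = field(default_factory=dict)
    protein_index: dict[str, int] = field(default_factory=dict)
    disease_index: dict[str, int] = field(default_factory=dict)

    def mutation_token(self, triple: MutationTriple) -> str:
        if triple not in self.mutation_index:
            self.mutation_index[triple] = len(self.mutation_index)
        return f"MUT{self.mutation_index[triple]}"

    def fallback_token(self, prefix: str, table: dict[str, int], key: str) -> str:
        if key not in table:
            table[key] = len(table)
        return f"{prefix}{table[key]}"

    def triple_for_token(self, token: str) -> MutationTriple | None:
        for triple, idx in self.mutation_index.items():
            if f"MUT{idx}" == token:
                return triple
        return None


@dataclass
class Substitution:
    start: int          # span in the simplified text
    end: int
    token: str
    mention: EntityMention


@dataclass
class PlaceholderSentence:
    sentence: Sentence
    text: str
    substitutions: list[Substitution]
    doc_state: DocumentState

    @property
    def placeholder_map(self) -> dict[str, list[EntityMention]]:
        out: dict[str, list[EntityMention]] = {}
        for sub in self.substitutions:
            out.setdefault(sub.token, []).append(sub.mention)
        return out

    @property
    def mutation_index(self) -> dict[MutationTriple, int]:
        return self.doc_state.mutation_index

    def tokens_of_class(self, eclass: str) -> list[str]:
        seen = dict.fromkeys(
            s.token for s in self.substitutions if s.mention.eclass == eclass)
        return list(seen)


def placeholder_token(mention: EntityMention, doc_state: DocumentState,
                      lexicons: LexiconSet | None = None) -> str:
    """The placeholder a mention is replaced with."""
    if mention.eclass == MUTATION:
        return doc_state.mutation_token(mention.mutation)
    if mention.eclass == PROTEIN:
        mnemonic = _mnemonic_for(mention, lexicons)
        if mnemonic:
            return _sanitize(mnemonic)
        key = mention.surface.lower()
        return doc_state.fallback_token("PROT", doc_state.protein_index, key)
    if mention.eclass == DISEASE:
        mesh = _mesh_for(mention)
        if mesh:
            return _sanitize(mesh)
        key = mention.surface.lower()
        return doc_state.fallback_token("DIS", doc_state.disease_index, key)
    raise ValueError(f"unknown entity class {mention.eclass!r}")


def _mnemonic_for(mention: EntityMention, lexicons: LexiconSet | None) -> str | None:
    for i in mention.ids:
        if re.fullmatch(r"[A-Z0-9]{1,6}_[A-Z0-9]{1,6}", i):
            return i
    if lexicons is not None:
        for i in mention.ids:
            if i in lexicons.entrez_to_mnemonic:
                return lexicons.entrez_to_mnemonic[i]
    return None


def _mesh_for(mention: EntityMention) -> str | None:
    for i in mention.ids:
        i = i.removeprefix("MESH:")
        if re.fullmatch(r"[CD]\d{6,9}", i):
            return i
    return None


def substitute_entities(sentence: Sentence, mentions: list[EntityMention],
                        doc_state: DocumentState,
                        lexicons: LexiconSet | None = None) -> PlaceholderSentence:
    """Build the simplified sentence for parsing.

    *mentions* must already be merged (non-overlapping); overlap here is
    a contract violation and raises.  Sets ``mention.token`` on every
    substituted mention as a side effect.
    """
    ordered = sorted((m for m in mentions if m.sentence_index == sentence.index),
                     key=lambda m: m.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping mentions survived merging: {a.surface!r} / {b.surface!r}")

    pieces: list[str] = []
    subs: list[Substitution] = []
    cursor = 0
    out_len = 0
    for m in ordered:
        pieces.append(sentence.text[cursor:m.start])
        out_len += m.start - cursor
        token = placeholder_token(m, doc_state, lexicons)
        m.token = token
        subs.append(Substitution(out_len, out_len + len(token), token, m))
        pieces.append(token)
        out_len += len(token)
        cursor = m.end
    pieces.append(sentence.text[cursor:])
    return PlaceholderSentence(sentence=sentence, text="".join(pieces),
                               substitutions=subs, doc_state=doc_state)


def desubstitute(ps: PlaceholderSentence) -> str:
    """Apply the reverse map: reproduces the original sentence exactly."""
    text = ps.text
    for sub in sorted(ps.substitutions, key=lambda s: s.start, reverse=True):
        text = text[:sub.start] + sub.mention.surface + text[sub.end:]
    return text
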