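"""Entity detection and normalization: substitution grammar, dictionary
tagging, abbreviation propagation, mention merging."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutrel import (DISEASE, Document, LexiconSet, MutationTriple, PROTEIN,
                    detect_abbreviations, detect_mutations, merge_mentions,
                    tag_dictionary)
from mutrel.entity_layer import EntityMention, parse_mutation_string
from mutrel.residues import THREE_TO_ONE


@pytest.mark.parametrize("text,expected", [
    ("A presenilin 1 mutation (Ser169Pro)", [("Ser", 169, "Pro")]),
    ("mutations R203C and T275M", [("Arg", 203, "Cys"), ("Thr", 275, "Met")]),
    ("JAK2 V617F", [("Val", 617, "Phe")]),
    ("the kinase domain", []),
    ("carrying p.V617F", [("Val", 617, "Phe")]),
    ("an aspartate 399 to asparagine change", [("Asp", 399, "Asn")]),
    ("the Asp399→Asn substitution", [("Asp", 399, "Asn")]),
    ("variant SER-409", []),                      # not a substitution
    ("Val (GTG) to Val (GTC)", []),               # codon spelling: standard grammar misses it
    ("IL2RA and the A2B receptor", []),           # identifier look-alikes suppressed
    ("a Glu318Gly polymorphism", [("Glu", 318, "Gly")]),
])
def test_substitution_grammar(text, expected):
    found = [(m.mutation.wt, m.mutation.pos, m.mutation.mut)
             for m in detect_mutations(text)]
    assert found == expected


def test_wild_type_equal_to_mutant_is_allowed():
    # silent substitutions do occur in text and must not be rejected
    [m] = detect_mutations("the V460V change")
    assert (m.mutation.wt, m.mutation.mut) == ("Val", "Val")


def test_codon_level_pattern_only_with_extended_grammar():
    text = "codon 444, Leu (CTG) to Pro (CCG)"
    assert detect_mutations(text) == []
    [m] = detect_mutations(text, extended=True)
    assert (m.mutation.wt, m.mutation.pos, m.mutation.mut) == ("Leu", 444, "Pro")


def test_overlapping_matches_resolve_to_longest():
    # the spelled form spans more characters than the compact form inside it
    [m] = detect_mutations("aspartate 399 to asparagine")
    assert m.surface == "aspartate 399 to asparagine"


@settings(max_examples=200, deadline=None, derandomize=True)
@given(wt=st.sampled_from(sorted(THREE_TO_ONE)),
       pos=st.integers(min_value=1, max_value=5000),
       mut=st.sampled_from(sorted(THREE_TO_ONE)))
def test_triple_one_letter_round_trip(wt, pos, mut):
    """Serializing a triple in 1-letter form and re-detecting recovers it."""
    triple = MutationTriple(wt, pos, mut)
    [m] = detect_mutations(f"the {triple.short()} variant")
    assert m.mutation == triple
    assert parse_mutation_string(triple.short()) == triple


@pytest.fixture
def lexicons():
    return LexiconSet(
        protein_names={"presenilin 1": ("PSN1_HUMAN", "5663")},
        disease_names={"early onset ad": "D000544", "myoclonic seizures": "D004831",
                       "multiple epiphyseal dysplasia": "D010009"},
        mesh_to_omim={"D000544": frozenset({"104300"})},
        signal_lengths={"PSN1_HUMAN": 0},
    )


def test_tag_dictionary_protein(lexicons):
    [m] = tag_dictionary("the presenilin 1 mutation", lexicons, PROTEIN)
    assert m.surface == "presenilin 1"
    assert m.ids == ("PSN1_HUMAN", "5663")


def test_tag_dictionary_two_diseases(lexicons):
    found = tag_dictionary("early-onset AD and myoclonic seizures", lexicons, DISEASE)
    assert [m.ids for m in found] == [("D000544",), ("D004831",)]


def test_tag_dictionary_no_hit(lexicons):
    assert tag_dictionary("an unrelated sentence", lexicons, DISEASE) == []


def test_abbreviation_detection_propagates_class(lexicons):
    doc = Document.build(
        "9", "Skeletal disorders.",
        "We describe multiple epiphyseal dysplasia (MED) in a family. "
        "A second patient with MED had club foot.")
    mentions = []
    for sent in doc.sentences:
        mentions.extend(tag_dictionary(sent, lexicons, DISEASE, pmid="9"))
    pairs = detect_abbreviations(doc, mentions)
    assert ("MED", "multiple epiphyseal dysplasia") in pairs
    short_forms = [m for m in mentions if m.surface == "MED"]
    assert short_forms and all(m.eclass == DISEASE and m.ids == ("D010009",)
                               for m in short_forms)
    # propagation reaches the later sentence
    assert any(m.sentence_index == 2 for m in short_forms)


def test_abbreviation_in_order_character_condition():
    # 'g' does not occur in "Pro", so (CCG) cannot abbreviate it
    doc = Document.build("9", "Codon usage.", "A change of Pro (CCG) was seen.")
    mentions = []
    pairs = detect_abbreviations(doc, mentions)
    assert pairs == []


def test_abbreviation_document_without_parentheses():
    doc = Document.build("9", "Plain title.", "No parentheses here.")
    assert detect_abbreviations(doc, []) == []


def _pm(start, end, surface, eclass=PROTEIN, ids=(), source="a"):
    return EntityMention(pmid="1", sentence_index=0, start=start, end=end,
                         surface=surface, eclass=eclass, ids=ids, source=source)


def test_merge_overlapping_same_class_takes_longest_span_and_unions_ids():
    merged = merge_mentions(
        [_pm(0, 10, "presenilin", ids=("5663",))],
        [_pm(0, 12, "presenilin 1", ids=("PSN1_HUMAN",), source="b")],
    )
    assert len(merged) == 1
    assert merged[0].span == (0, 12)
    assert set(merged[0].ids) == {"5663", "PSN1_HUMAN"}


def test_merge_keeps_disjoint_mentions():
    a, b = _pm(0, 4, "ABCD"), _pm(10, 14, "EFGH")
    assert [m.span for m in merge_mentions([a, b])] == [(0, 4), (10, 14)]


def test_merge_identical_span_cross_class_priority():
    """A span tagged both PROTEIN and DISEASE keeps the PROTEIN reading —
    the rule that surfaces in gene-symbol/disease-name clashes."""
    p = _pm(0, 5, "DTDST", eclass=PROTEIN, ids=("DTD_HUMAN",))
    d = _pm(0, 5, "DTDST", eclass=DISEASE, ids=("D010009",))
    merged = merge_mentions([p], [d])
    assert len(merged) == 1 and merged[0].eclass == PROTEIN


def test_merge_is_idempotent():
    lists = [
        [_pm(0, 10, "presenilin", ids=("5663",)), _pm(20, 25, "other", eclass=DISEASE)],
        [_pm(0, 12, "presenilin 1", ids=("PSN1_HUMAN",))],
    ]
    once = merge_mentions(*lists)
    twice = merge_mentions(once)
    assert [(m.span, m.eclass, m.ids) for m in once] == \
           [(m.span, m.eclass, m.ids) for m in twice]
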