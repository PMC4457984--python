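"""Format readers/writers: PubTator, CoNLL-U, BRAT, lexicons."""

import pytest

from mutrel import (DISEASE, MUTATION, PROTEIN, Document, load_lexicons, read_brat,
                    read_conllu, read_pubtator, split_sentences, write_brat,
                    write_pubtator)
from mutrel.entity_layer import EntityMention, MutationTriple


def test_read_pubtator_single_mutation_annotation(tmp_path):
    """A minimal pipe/tab document with one mutation annotation yields one
    normalized MUTATION mention at sentence-level offsets."""
    p = tmp_path / "c.pubtator"
    p.write_text("1|t|X\n1|a|JAK2 V617F found.\n1\t2\t12\tJAK2 V617F\tMutation\tp.V617F\n\n")
    [(doc, mentions)] = read_pubtator(p)
    assert doc.pmid == "1" and doc.text == "X JAK2 V617F found."
    assert len(mentions) == 1
    m = mentions[0]
    assert m.eclass == MUTATION
    assert (m.mutation.wt, m.mutation.pos, m.mutation.mut) == ("Val", 617, "Phe")
    # title is sentence 0, so the annotation lands in sentence 1
    assert m.sentence_index == 1
    sent = doc.sentences[m.sentence_index]
    assert sent.text[m.start:m.end] == "JAK2 V617F"


def test_read_pubtator_empty_file(tmp_path):
    p = tmp_path / "empty.pubtator"
    p.write_text("")
    assert read_pubtator(p) == []


def test_read_pubtator_rejects_span_mismatch_keeps_document(tmp_path, caplog):
    p = tmp_path / "c.pubtator"
    p.write_text("1|t|X\n1|a|JAK2 V617F found.\n1\t2\t12\tWRONG TEXT\tMutation\tp.V617F\n\n")
    with caplog.at_level("WARNING"):
        [(doc, mentions)] = read_pubtator(p)
    assert doc.pmid == "1"
    assert mentions == []


def test_read_pubtator_skips_unknown_types(tmp_path):
    p = tmp_path / "c.pubtator"
    p.write_text("1|t|X\n1|a|Mice were studied.\n1\t2\t6\tMice\tSpecies\t10090\n\n")
    [(_, mentions)] = read_pubtator(p)
    assert mentions == []


def test_pubtator_round_trip_is_idempotent(tmp_path, synthetic_corpus):
    """read -> write -> read preserves every span and entity class."""
    src = [(d, synthetic_corpus.mentions_by_pmid[d.pmid])
           for d in synthetic_corpus.documents]
    out = tmp_path / "roundtrip.pubtator"
    write_pubtator(src, out)
    again = read_pubtator(out)
    assert len(again) == len(src)
    for (d1, m1), (d2, m2) in zip(src, again):
        assert d1.text == d2.text
        assert [(m.sentence_index, m.start, m.end, m.eclass) for m in m1] == \
               [(m.sentence_index, m.start, m.end, m.eclass) for m in m2]


def test_every_mention_matches_document_text(synthetic_corpus):
    for doc in synthetic_corpus.documents:
        for m in synthetic_corpus.mentions_by_pmid[doc.pmid]:
            sent = doc.sentences[m.sentence_index]
            assert sent.text[m.start:m.end] == m.surface


def test_split_sentences_never_splits_inside_parentheses():
    text = "A mutation (Ser169Pro. Severe) was found. Another sentence."
    spans = split_sentences(text)
    assert [text[s:e] for s, e in spans] == [
        "A mutation (Ser169Pro. Severe) was found.", "Another sentence."]


def test_document_sentences_cover_their_spans():
    doc = Document.build("1", "A title.", "First sentence. Second sentence.")
    assert doc.sentences[0].text == "A title."
    for s in doc.sentences:
        assert doc.text[s.start:s.end] == s.text


CONLLU_SMALL = """\
# pmid = 5
# sent_id = 0
1\tthe\tthe\t_\t_\t_\t2\tdet\t_\t_
2\tprotein\tprotein\t_\t_\t_\t0\troot\t_\t_
3\tbinds\tbind\t_\t_\t_\t2\tacl\t_\t_

# pmid = 5
# sent_id = 1
1\tshort\tshort\t_\t_\t_\t0\troot\t_\t_
"""


def test_read_conllu_heads_become_edges(tmp_path):
    p = tmp_path / "x.conllu"
    p.write_text(CONLLU_SMALL)
    graphs = read_conllu(p)
    assert set(graphs) == {("5", 0), ("5", 1)}
    g = graphs[("5", 0)]
    assert g.nodes == {1: "the", 2: "protein", 3: "binds"}
    assert g.graph.number_of_edges() == 2
    assert g.graph.has_edge(2, 1) and g.graph.has_edge(2, 3)


def test_read_conllu_skips_block_with_bad_head(tmp_path):
    bad = CONLLU_SMALL.replace("2\tdet", "9\tdet")
    p = tmp_path / "x.conllu"
    p.write_text(bad)
    graphs = read_conllu(p)
    assert set(graphs) == {("5", 1)}


def test_write_brat_mention_line_and_round_trip(tmp_path):
    doc = Document.build("7", "A presenilin 1 mutation.", "R203C causes disease here.")
    mentions = [
        EntityMention(pmid="7", sentence_index=0, start=2, end=14,
                      surface="presenilin 1", eclass=PROTEIN, ids=("PSN1_HUMAN",)),
        EntityMention(pmid="7", sentence_index=1, start=0, end=5, surface="R203C",
                      eclass=MUTATION, mutation=MutationTriple("Arg", 203, "Cys")),
        EntityMention(pmid="7", sentence_index=1, start=13, end=20,
                      surface="disease", eclass=DISEASE, ids=("D000001",)),
    ]
    ann = tmp_path / "doc.ann"
    write_brat(doc, mentions, [(0, 1, 2)], ann)
    lines = ann.read_text().splitlines()
    assert lines[0] == "T1\tProtein 2 14\tpresenilin 1"
    spans, relations = read_brat(ann)
    assert spans["T1"] == ("Protein", 2, 14, "presenilin 1")
    assert relations == [frozenset({"T1", "T2", "T3"})]


def test_write_brat_without_relations_has_only_t_lines(tmp_path):
    doc = Document.build("7", "A presenilin 1 mutation.", "Nothing else.")
    mentions = [EntityMention(pmid="7", sentence_index=0, start=2, end=14,
                              surface="presenilin 1", eclass=PROTEIN)]
    ann = tmp_path / "doc.ann"
    write_brat(doc, mentions, [], ann)
    assert all(line.startswith("T") for line in ann.read_text().splitlines())


def test_load_lexicons(synthetic_corpus, tmp_path):
    lex = synthetic_corpus.lexicons
    assert lex.lookup_protein("Mutadorin 3") == ("MTD3_HUMAN", "5003")
    assert lex.lookup_disease("GRANULOPATHY 5") == "D650005"
    assert lex.omim_for_mesh("D650000") == frozenset({"600000", "610000", "620000"})
    assert lex.signal_lengths["MTD0_HUMAN"] >= 0
    # unmapped MeSH id -> empty set
    assert lex.omim_for_mesh("D999999") == frozenset()


def test_load_lexicons_missing_file_names_it(tmp_path):
    (tmp_path / "proteins.tsv").write_text("name\tuniprot\tentrez\n")
    with pytest.raises(FileNotFoundError, match="diseases.tsv"):
        load_lexicons(tmp_path)


def test_lexicon_examples_from_printed_rows(tmp_path):
    for name, content in {
        "proteins.tsv": "presenilin 1\tPSN1_HUMAN\t5663\n",
        "diseases.tsv": "early-onset AD\tD000544\n",
        "mesh_omim.tsv": "C566471\t610476\n",
        "signal_peptides.tsv": "PSN1_HUMAN\t0\n",
    }.items():
        (tmp_path / name).write_text(content)
    lex = load_lexicons(tmp_path)
    assert lex.lookup_protein("Presenilin 1") == ("PSN1_HUMAN", "5663")
    assert lex.omim_for_mesh("C566471") == frozenset({"610476"})
    # no triggers file -> built-in trigger list
    assert lex.trigger_class("mutational") == MUTATION
    assert lex.trigger_class("patients") == DISEASE
    assert lex.trigger_class("kinase") is None
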