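"""Gold construction, corpus filter/split, scoring, error categories."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import run_all_systems

from mutrel import (Document, EvalResult, categorize_recall_errors, f_measure,
                    filter_corpus, parse_uniprot_variants, score, split_corpus,
                    tuples_from_gold)
from mutrel.association import prepare_document
from mutrel.corpus_io import DISEASE, MUTATION, PROTEIN
from mutrel.entity_layer import EntityMention, MutationTriple
from mutrel.gold_eval import ENTITY_ABSENT, EXTRACTION_MISS, read_gold_tsv, write_gold_tsv

APC_SPROT = """\
ID   APC_HUMAN               Reviewed;        2843 AA.
AC   P25054;
DT   01-MAY-1992, integrated into UniProtKB/Swiss-Prot.
DE   RecName: Full=Adenomatous polyposis coli protein;
GN   Name=APC;
OS   Homo sapiens (Human).
OC   Eukaryota; Metazoa.
OX   NCBI_TaxID=9606;
RN   [1]
RP   VARIANTS.
RX   PubMed=10666372;
RA   Doe J.;
RT   "Synthetic record.";
RL   J. Synth 1:1-1(2000).
CC   -!- DISEASE: Medulloblastoma (MDB) [MIM:155255]: A cerebellar tumor.
CC       {ECO:0000269|PubMed:10666372}.
DR   MIM; 155255; phenotype.
FT   VARIANT         1296
FT                   /note="A -> V (in MDB)"
FT                   /evidence="ECO:0000269|PubMed:10666372"
FT   VARIANT         1307
FT                   /note="I -> K"
FT                   /evidence="ECO:0000269|PubMed:9973276"
SQ   SEQUENCE   2843 AA;  311646 MW;  ABCDEF1234567890 CRC64;
     MAAAA
//
"""


def test_parse_variant_without_signal_keeps_position():
    records = parse_uniprot_variants(APC_SPROT)
    [r] = [r for r in records if r.omim_id]
    assert (r.uniprot_id, r.wt, r.pos_db, r.pos_text_expected, r.mut,
            r.omim_id, r.pmid) == ("APC_HUMAN", "Ala", 1296, 1296, "Val",
                                   "155255", "10666372")


def test_parse_variant_with_signal_subtracts_length(entity_absent_sprot):
    records = parse_uniprot_variants(entity_absent_sprot)
    assert len(records) == 4
    by_pos = {r.pos_db: r for r in records}
    assert by_pos[409].pos_text_expected == 370
    assert by_pos[448].pos_text_expected == 409
    assert by_pos[483].pos_text_expected == 444
    assert by_pos[502].pos_text_expected == 463
    assert all(r.omim_id == "230800" for r in records)


def test_variant_without_disease_link_enters_pm_gold_only():
    records = parse_uniprot_variants(APC_SPROT)
    [r] = [r for r in records if r.omim_id is None]
    assert (r.wt, r.pos_db, r.mut, r.pmid) == ("Ile", 1307, "Lys", "9973276")
    gold_tuples = tuples_from_gold(records)
    assert all(t.pos_norm != 1307 for t in gold_tuples)  # excluded from ternary gold
    pm = score(gold_tuples, records, "PM")
    assert pm.fn == 1  # the disease-less record is part of the PM gold


def test_gold_tsv_round_trip(tmp_path, entity_absent_sprot):
    records = parse_uniprot_variants(entity_absent_sprot)
    path = tmp_path / "gold.tsv"
    write_gold_tsv(records, path)
    assert read_gold_tsv(path) == records


def _doc_with(classes):
    doc = Document.build("1", "T.", "A.")
    mentions = []
    for i, c in enumerate(classes):
        triple = MutationTriple("Ala", 10, "Val") if c == MUTATION else None
        mentions.append(EntityMention(pmid="1", sentence_index=0, start=0, end=1,
                                      surface="T", eclass=c, mutation=triple))
    return doc, mentions


def test_filter_corpus_requires_all_three_classes():
    complete = _doc_with([PROTEIN, MUTATION, DISEASE])
    partial = _doc_with([PROTEIN, DISEASE])
    assert filter_corpus([complete, partial]) == [complete]
    assert filter_corpus([]) == []


@pytest.mark.parametrize("n,frac,expected", [(720, 0.8, (576, 144)), (10, 0.8, (8, 2))])
def test_split_corpus_sizes(n, frac, expected):
    dev, test = split_corpus(range(n), frac, seed=3)
    assert (len(dev), len(test)) == expected
    assert sorted(dev + test) == list(range(n))


def test_split_corpus_is_deterministic_given_seed():
    a = split_corpus(range(100), 0.8, seed=5)
    b = split_corpus(range(100), 0.8, seed=5)
    c = split_corpus(range(100), 0.8, seed=6)
    assert a == b
    assert a != c


def test_split_corpus_rejects_degenerate_fraction():
    with pytest.raises(ValueError):
        split_corpus(range(10), 1.0)


def test_score_on_gold_projection_is_perfect(synthetic_corpus):
    """score(gold, gold) is a fixed point: 100/100/100 for every type."""
    gold = synthetic_corpus.gold
    tuples = tuples_from_gold(gold)
    for rtype in ("PMD", "PM", "MD", "PD"):
        res = score(tuples, [g for g in gold], rtype)
        assert (res.precision, res.recall, res.f_measure) == (100.0, 100.0, 100.0)


@pytest.mark.parametrize("p,r,f", [(82.3, 80.8, 81.5), (71.6, 58.3, 64.3),
                                   (75.8, 59.6, 66.7)])
def test_f_measure_matches_reported_rates(p, r, f):
    """F recomputed from operating points via counts constructed to give
    exactly those precision/recall rates."""
    res = EvalResult.from_counts(tp=p * r, fp=r * (100 - p), fn=p * (100 - r))
    assert res.precision == pytest.approx(p)
    assert res.recall == pytest.approx(r)
    assert round(res.f_measure, 1) == f


def test_score_zero_guards():
    res = score([], [], "PMD")
    assert (res.precision, res.recall, res.f_measure) == (0.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        score([], [], "XY")


@settings(max_examples=200, deadline=None, derandomize=True)
@given(p=st.floats(0, 100), r=st.floats(0, 100))
def test_f_measure_bounds(p, r):
    f = f_measure(p, r)
    assert min(p, r) - 1e-9 <= f <= max(p, r) + 1e-9
    if p == r:
        assert f == pytest.approx(p)


def test_position_match_accepts_either_coordinate_space(entity_absent_sprot):
    records = parse_uniprot_variants(entity_absent_sprot)
    gold = [r for r in records if r.pos_db == 409]
    text_space = tuples_from_gold(gold)[0]
    # report the tuple in raw text coordinates (no signal adjustment known)
    unadjusted = type(text_space)(
        pmid=text_space.pmid, uniprot_id=text_space.uniprot_id, wt=text_space.wt,
        pos_text=370, pos_norm=370, mut=text_space.mut,
        omim_ids=text_space.omim_ids)
    res = score([unadjusted], gold, "PMD")
    assert (res.tp, res.fp, res.fn) == (1, 0, 0)


def test_recall_errors_split_into_absent_and_missed(entity_absent_corpus,
                                                    entity_absent_sprot):
    """The four variants and the disease are in the abstract but the
    protein is not: four ENTITY_ABSENT(protein) errors."""
    corpus = entity_absent_corpus
    gold = parse_uniprot_variants(entity_absent_sprot)
    doc = corpus.documents[0]
    prepared = prepare_document(doc, corpus.parses, corpus.lexicons,
                                corpus.mentions_by_pmid[doc.pmid])
    categories = categorize_recall_errors(gold, {doc.pmid: prepared.mentions},
                                          corpus.lexicons)
    assert len(categories) == 4
    assert all(c.kind == ENTITY_ABSENT and c.missing == "protein"
               for c in categories.values())


def test_present_entities_with_no_extraction_is_extraction_miss(identity_link_corpus):
    corpus = identity_link_corpus
    doc = corpus.documents[0]
    prepared = prepare_document(doc, corpus.parses, corpus.lexicons,
                                corpus.mentions_by_pmid[doc.pmid])
    categories = categorize_recall_errors(corpus.gold, {doc.pmid: prepared.mentions},
                                          corpus.lexicons)
    assert all(c.kind == EXTRACTION_MISS for c in categories.values())


def test_empty_false_negative_set(identity_link_corpus):
    assert categorize_recall_errors([], {}, identity_link_corpus.lexicons) == {}


def test_recall_ordering_matches_variant_capability(synthetic_corpus):
    """recall(S1) >= recall(S2) >= recall(S3) and
    recall(S5) >= recall(S4) >= recall(S3)."""
    outputs = run_all_systems(synthetic_corpus)
    recalls = {s: score(t, synthetic_corpus.gold, "PMD").recall
               for s, t in outputs.items()}
    assert recalls["S1"] >= recalls["S2"] >= recalls["S3"]
    assert recalls["S5"] >= recalls["S4"] >= recalls["S3"]
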