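"""Shared fixtures: small hand-built synthetic corpora exercising each
discourse mechanism, plus a generated corpus.

All corpora here are synthetic replicas built by hand for testing; the
dependency parses are fixture CoNLL-U blocks over the simplified
(placeholder) sentences.
"""

import pytest

from mutrel import Corpus, CorpusSpec, generate_corpus, load_corpus


def _write_lexicons(tmp, proteins, diseases, mesh_omim, signals, triggers=None):
    lexdir = tmp / "lexicons"
    lexdir.mkdir()
    (lexdir / "proteins.tsv").write_text(
        "name\tuniprot\tentrez\n" + "".join(f"{n}\t{u}\t{e}\n" for n, u, e in proteins))
    (lexdir / "diseases.tsv").write_text(
        "name\tmesh\n" + "".join(f"{n}\t{m}\n" for n, m in diseases))
    (lexdir / "mesh_omim.tsv").write_text(
        "mesh\tomim\n" + "".join(f"{m}\t{o}\n" for m, o in mesh_omim))
    (lexdir / "signal_peptides.tsv").write_text(
        "uniprot\tlength\n" + "".join(f"{u}\t{s}\n" for u, s in signals))
    if triggers:
        (lexdir / "triggers.tsv").write_text(
            "word\tclass\n" + "".join(f"{w}\t{c}\n" for w, c in triggers))
    return lexdir


def _build_case(tmp, pubtator_text, conllu_text, lexicon_args, gold_text=None) -> Corpus:
    pub = tmp / "corpus.pubtator"
    pub.write_text(pubtator_text)
    conllu = None
    if conllu_text is not None:
        conllu = tmp / "corpus.conllu"
        conllu.write_text(conllu_text)
    lexdir = _write_lexicons(tmp, **lexicon_args)
    gold = None
    if gold_text is not None:
        gold = tmp / "gold.tsv"
        gold.write_text(gold_text)
    return load_corpus(pub, conllu, lexdir, gold)


# ---------------------------------------------------------------------------
# apposition sentence: all three entities share one sentence

APPOSITION_PUBTATOR = (
    "100001|t|Clinical report.\n"
    "100001|a|A presenilin 1 mutation (Ser169Pro) associated with "
    "early-onset AD and myoclonic seizures.\n"
    "\n"
)

APPOSITION_CONLLU = """\
# pmid = 100001
# sent_id = 0
1\tClinical\tclinical\t_\t_\t_\t2\tamod\t_\t_
2\treport\treport\t_\t_\t_\t0\troot\t_\t_
3\t.\t.\t_\t_\t_\t2\tpunct\t_\t_

# pmid = 100001
# sent_id = 1
1\tA\ta\t_\t_\t_\t3\tdet\t_\t_
2\tPSN1_HUMAN\tpsn1_human\t_\t_\t_\t3\tcompound\t_\t_
3\tmutation\tmutation\t_\t_\t_\t7\tnsubj\t_\t_
4\t(\t(\t_\t_\t_\t5\tpunct\t_\t_
5\tMUT0\tmut0\t_\t_\t_\t3\tappos\t_\t_
6\t)\t)\t_\t_\t_\t5\tpunct\t_\t_
7\tassociated\tassociate\t_\t_\t_\t0\troot\t_\t_
8\twith\twith\t_\t_\t_\t9\tcase\t_\t_
9\tD000544\td000544\t_\t_\t_\t7\tobl\t_\t_
10\tand\tand\t_\t_\t_\t11\tcc\t_\t_
11\tD004831\td004831\t_\t_\t_\t9\tconj\t7:obl:with\t_
12\t.\t.\t_\t_\t_\t7\tpunct\t_\t_
"""

APPOSITION_GOLD = (
    "pmid\tuniprot_id\twt\tpos_db\tpos_text\tmut\tomim_id\tlabel\n"
    "100001\tPSN1_HUMAN\tSer\t169\t169\tPro\t104300\tS2_RECOVERABLE\n"
    "100001\tPSN1_HUMAN\tSer\t169\t169\tPro\t254800\tS2_RECOVERABLE\n"
)


@pytest.fixture
def apposition_corpus(tmp_path) -> Corpus:
    """One sentence holding protein, mutation (apposition in parentheses)
    and two conjoined diseases."""
    return _build_case(
        tmp_path, APPOSITION_PUBTATOR, APPOSITION_CONLLU,
        dict(
            proteins=[("presenilin 1", "PSN1_HUMAN", "5663")],
            diseases=[("early-onset AD", "D000544"), ("myoclonic seizures", "D004831")],
            mesh_omim=[("D000544", "104300"), ("D004831", "254800")],
            signals=[("PSN1_HUMAN", "0")],
        ),
        gold_text=APPOSITION_GOLD,
    )


# ---------------------------------------------------------------------------
# entity-identity link: disease+protein in one sentence, protein+two
# mutations in another; the shared protein links the graphs

IDENTITY_PUBTATOR = (
    "200001|t|Case report.\n"
    "200001|a|Mechanistic insights into arrhythmogenic right ventricular "
    "cardiomyopathy caused by desmocollin-2 mutations. The two missense "
    "mutations (desmocollin-2 R203C and T275M) have been functionally "
    "characterized.\n"
    "\n"
)

IDENTITY_CONLLU = """\
# pmid = 200001
# sent_id = 0
1\tCase\tcase\t_\t_\t_\t2\tcompound\t_\t_
2\treport\treport\t_\t_\t_\t0\troot\t_\t_
3\t.\t.\t_\t_\t_\t2\tpunct\t_\t_

# pmid = 200001
# sent_id = 1
1\tMechanistic\tmechanistic\t_\t_\t_\t2\tamod\t_\t_
2\tinsights\tinsight\t_\t_\t_\t0\troot\t_\t_
3\tinto\tinto\t_\t_\t_\t4\tcase\t_\t_
4\tC566471\tc566471\t_\t_\t_\t2\tnmod\t_\t_
5\tcaused\tcause\t_\t_\t_\t4\tacl\t_\t_
6\tby\tby\t_\t_\t_\t8\tcase\t_\t_
7\tDSC2_HUMAN\tdsc2_human\t_\t_\t_\t8\tcompound\t_\t_
8\tmutations\tmutation\t_\t_\t_\t5\tobl\t_\t_
9\t.\t.\t_\t_\t_\t2\tpunct\t_\t_

# pmid = 200001
# sent_id = 2
1\tThe\tthe\t_\t_\t_\t4\tdet\t_\t_
2\ttwo\ttwo\t_\t_\t_\t4\tnummod\t_\t_
3\tmissense\tmissense\t_\t_\t_\t4\tamod\t_\t_
4\tmutations\tmutation\t_\t_\t_\t14\tnsubj\t_\t_
5\t(\t(\t_\t_\t_\t6\tpunct\t_\t_
6\tDSC2_HUMAN\tdsc2_human\t_\t_\t_\t4\tappos\t_\t_
7\tMUT0\tmut0\t_\t_\t_\t6\tappos\t_\t_
8\tand\tand\t_\t_\t_\t9\tcc\t_\t_
9\tMUT1\tmut1\t_\t_\t_\t7\tconj\t6:appos\t_
10\t)\t)\t_\t_\t_\t6\tpunct\t_\t_
11\thave\thave\t_\t_\t_\t14\taux\t_\t_
12\tbeen\tbe\t_\t_\t_\t14\taux\t_\t_
13\tfunctionally\tfunctionally\t_\t_\t_\t14\tadvmod\t_\t_
14\tcharacterized\tcharacterize\t_\t_\t_\t0\troot\t_\t_
15\t.\t.\t_\t_\t_\t14\tpunct\t_\t_
"""

IDENTITY_GOLD = (
    "pmid\tuniprot_id\twt\tpos_db\tpos_text\tmut\tomim_id\tlabel\n"
    "200001\tDSC2_HUMAN\tArg\t275\t203\tCys\t610476\tS4_RECOVERABLE\n"
    "200001\tDSC2_HUMAN\tThr\t347\t275\tMet\t610476\tS4_RECOVERABLE\n"
)


@pytest.fixture
def identity_link_corpus(tmp_path) -> Corpus:
    # the 72-residue signal length makes text position 203 normalize to 275
    return _build_case(
        tmp_path, IDENTITY_PUBTATOR, IDENTITY_CONLLU,
        dict(
            proteins=[("desmocollin-2", "DSC2_HUMAN", "1824")],
            diseases=[("arrhythmogenic right ventricular cardiomyopathy", "C566471")],
            mesh_omim=[("C566471", "610476")],
            signals=[("DSC2_HUMAN", "72")],
        ),
        gold_text=IDENTITY_GOLD,
    )


# ---------------------------------------------------------------------------
# trigger link: "Mutational" headline resolving to a mutation in a later
# sentence (the documented false-positive mechanism)

TRIGGER_PUBTATOR = (
    "300001|t|Leukemia genetics.\n"
    "300001|a|Mutational spectrum analysis of chronic myelomonocytic leukemia "
    "includes genes associated with epigenetic regulation. JAK2 V617F was "
    "present in 1 % of patients.\n"
    "\n"
)

TRIGGER_CONLLU = """\
# pmid = 300001
# sent_id = 0
1\tLeukemia\tleukemia\t_\t_\t_\t2\tcompound\t_\t_
2\tgenetics\tgenetics\t_\t_\t_\t0\troot\t_\t_
3\t.\t.\t_\t_\t_\t2\tpunct\t_\t_

# pmid = 300001
# sent_id = 1
1\tMutational\tmutational\t_\t_\t_\t3\tamod\t_\t_
2\tspectrum\tspectrum\t_\t_\t_\t3\tcompound\t_\t_
3\tanalysis\tanalysis\t_\t_\t_\t6\tnsubj\t_\t_
4\tof\tof\t_\t_\t_\t5\tcase\t_\t_
5\tD015477\td015477\t_\t_\t_\t3\tnmod\t_\t_
6\tincludes\tinclude\t_\t_\t_\t0\troot\t_\t_
7\tgenes\tgene\t_\t_\t_\t6\tobj\t_\t_
8\tassociated\tassociate\t_\t_\t_\t7\tacl\t_\t_
9\twith\twith\t_\t_\t_\t11\tcase\t_\t_
10\tepigenetic\tepigenetic\t_\t_\t_\t11\tamod\t_\t_
11\tregulation\tregulation\t_\t_\t_\t8\tobl\t_\t_
12\t.\t.\t_\t_\t_\t6\tpunct\t_\t_

# pmid = 300001
# sent_id = 2
1\tJAK2_HUMAN\tjak2_human\t_\t_\t_\t2\tcompound\t_\t_
2\tMUT0\tmut0\t_\t_\t_\t4\tnsubj\t_\t_
3\twas\tbe\t_\t_\t_\t4\tcop\t_\t_
4\tpresent\tpresent\t_\t_\t_\t0\troot\t_\t_
5\tin\tin\t_\t_\t_\t7\tcase\t_\t_
6\t1\t1\t_\t_\t_\t7\tnummod\t_\t_
7\t%\t%\t_\t_\t_\t4\tobl\t_\t_
8\tof\tof\t_\t_\t_\t9\tcase\t_\t_
9\tpatients\tpatient\t_\t_\t_\t7\tnmod\t_\t_
10\t.\t.\t_\t_\t_\t4\tpunct\t_\t_
"""


@pytest.fixture
def trigger_corpus(tmp_path) -> Corpus:
    """No gold: the trigger-derived triple is a deliberate false positive."""
    return _build_case(
        tmp_path, TRIGGER_PUBTATOR, TRIGGER_CONLLU,
        dict(
            proteins=[("JAK2", "JAK2_HUMAN", "3717")],
            diseases=[("chronic myelomonocytic leukemia", "D015477")],
            mesh_omim=[("D015477", "607785")],
            signals=[("JAK2_HUMAN", "0")],
        ),
        gold_text="pmid\tuniprot_id\twt\tpos_db\tpos_text\tmut\tomim_id\tlabel\n",
    )


# ---------------------------------------------------------------------------
# entity-absent abstract: four variants and the disease are mentioned,
# the gold protein never is

ABSENT_PUBTATOR = (
    "400001|t|Mutation analysis in Gaucher disease.\n"
    "400001|a|Four novel alleles Phe370Ser, Leu409His, Ala444Pro and "
    "Arg463Cys were identified in patients with Gaucher disease.\n"
    "\n"
)

#: synthetic SwissProt-style flat record: 39-residue signal peptide,
#: four disease variants citing the abstract above
ABSENT_SPROT = """\
ID   GLCM_HUMAN              Reviewed;         536 AA.
AC   P04062;
DT   01-AUG-1988, integrated into UniProtKB/Swiss-Prot.
DE   RecName: Full=Lysosomal acid glucosylceramidase;
GN   Name=GBA1;
OS   Homo sapiens (Human).
OC   Eukaryota; Metazoa.
OX   NCBI_TaxID=9606;
RN   [1]
RP   VARIANTS.
RX   PubMed=400001;
RA   Doe J.;
RT   "Mutation analysis.";
RL   J. Synth 1:1-1(1995).
CC   -!- DISEASE: Gaucher disease (GD) [MIM:230800]: A lysosomal storage
CC       disease. {ECO:0000269|PubMed:400001}.
DR   MIM; 230800; phenotype.
FT   SIGNAL          1..39
FT                   /evidence="ECO:0000255"
FT   VARIANT         409
FT                   /note="F -> S (in GD)"
FT                   /evidence="ECO:0000269|PubMed:400001"
FT   VARIANT         448
FT                   /note="L -> H (in GD)"
FT                   /evidence="ECO:0000269|PubMed:400001"
FT   VARIANT         483
FT                   /note="A -> P (in GD)"
FT                   /evidence="ECO:0000269|PubMed:400001"
FT   VARIANT         502
FT                   /note="R -> C (in GD)"
FT                   /evidence="ECO:0000269|PubMed:400001"
SQ   SEQUENCE   536 AA;  59700 MW;  ABCDEF1234567890 CRC64;
     MAAAA
//
"""


@pytest.fixture
def entity_absent_corpus(tmp_path) -> Corpus:
    return _build_case(
        tmp_path, ABSENT_PUBTATOR, None,
        dict(
            proteins=[("glucocerebrosidase", "GLCM_HUMAN", "2629")],
            diseases=[("Gaucher disease", "D005776")],
            mesh_omim=[("D005776", "230800")],
            signals=[("GLCM_HUMAN", "39")],
        ),
    )


@pytest.fixture
def entity_absent_sprot() -> str:
    return ABSENT_SPROT


# ---------------------------------------------------------------------------
# generated corpus

@pytest.fixture(scope="session")
def synthetic_corpus(tmp_path_factory) -> Corpus:
    tmp = tmp_path_factory.mktemp("synth")
    paths = generate_corpus(CorpusSpec(n_docs=40, seed=11), tmp)
    return load_corpus(paths.pubtator, paths.conllu, paths.lexicon_dir, paths.gold)
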