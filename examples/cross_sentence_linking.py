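"""Cross-sentence entity-identity linking (variant S4).

A disease-protein sentence ("... cardiomyopathy caused by desmocollin-2
mutations") and a protein-mutation sentence share the protein token, so
their dependency graphs are linked and the binary relations compose into
ternary tuples.  The sentence-level variant S3 finds no ternary relation
here.  The 72-residue signal peptide moves text position 203 to database
position 275.
"""

import tempfile
from pathlib import Path

from mutrel import extract_corpus, load_corpus

PUBTATOR = (
    "200001|t|Case report.\n"
    "200001|a|Mechanistic insights into arrhythmogenic right ventricular "
    "cardiomyopathy caused by desmocollin-2 mutations. The two missense "
    "mutations (desmocollin-2 R203C and T275M) have been functionally "
    "characterized.\n\n"
)

CONLLU = """\
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

LEXICONS = {
    "proteins.tsv": "name\tuniprot\tentrez\ndesmocollin-2\tDSC2_HUMAN\t1824\n",
    "diseases.tsv": ("name\tmesh\narrhythmogenic right ventricular "
                     "cardiomyopathy\tC566471\n"),
    "mesh_omim.tsv": "mesh\tomim\nC566471\t610476\n",
    "signal_peptides.tsv": "uniprot\tlength\nDSC2_HUMAN\t72\n",
}


def main():
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        (tmp / "c.pubtator").write_text(PUBTATOR)
        (tmp / "c.conllu").write_text(CONLLU)
        (tmp / "lex").mkdir()
        for name, content in LEXICONS.items():
            (tmp / "lex" / name).write_text(content)
        corpus = load_corpus(tmp / "c.pubtator", tmp / "c.conllu", tmp / "lex")
        for system in ("S3", "S4"):
            tuples = extract_corpus(corpus, system)
            print(f"{system}: {len(tuples)} ternary tuple(s)")
            for t in tuples:
                print(f"  <{t.uniprot_id}, {t.wt}, {t.pos_text}, {t.pos_norm}, "
                      f"{t.mut}, {'|'.join(sorted(t.omim_ids))}>")
    print("\nS3 sees no sentence with all three entities; linking on the")
    print("shared protein placeholder composes both protein-mutation pairs")
    print("with the protein-disease relation from the first sentence.")


if __name__ == "__main__":
    main()
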