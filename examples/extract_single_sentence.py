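"""Single-sentence extraction: apposition + conjunction.

Builds a one-abstract corpus in which a protein, a point mutation (in
parenthetical apposition) and two conjoined diseases share a sentence,
then runs the sentence-level graph-traversal variant (S3).  The parse is
a fixture CoNLL-U block over the simplified sentence, including the
propagated-conjunction enhanced edge that makes the second disease
reachable.
"""

import tempfile
from pathlib import Path

from mutrel import extract_corpus, load_corpus

PUBTATOR = (
    "100001|t|Clinical report.\n"
    "100001|a|A presenilin 1 mutation (Ser169Pro) associated with "
    "early-onset AD and myoclonic seizures.\n\n"
)

CONLLU = """\
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

LEXICONS = {
    "proteins.tsv": "name\tuniprot\tentrez\npresenilin 1\tPSN1_HUMAN\t5663\n",
    "diseases.tsv": ("name\tmesh\nearly-onset AD\tD000544\n"
                     "myoclonic seizures\tD004831\n"),
    "mesh_omim.tsv": "mesh\tomim\nD000544\t104300\nD004831\t254800\n",
    "signal_peptides.tsv": "uniprot\tlength\nPSN1_HUMAN\t0\n",
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
        tuples = extract_corpus(corpus, "S3")

    print("S3 (single-sentence graph traversal) tuples:")
    for t in tuples:
        print(f"  <{t.uniprot_id}, {t.wt}, {t.pos_text}, {t.pos_norm}, {t.mut}, "
              f"{'|'.join(sorted(t.omim_ids))}>  pmid={t.pmid}")
    print("\nOne tuple per conjoined disease: the entities share the common")
    print("node 'mutation' on the dependency graph, and positions keep their")
    print("text value (no signal peptide on this protein).")


if __name__ == "__main__":
    main()
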