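"""Gold-standard construction from curated variant records.

Parses a SwissProt-style flat record carrying natural-variant features,
a disease cross-reference and cited PMIDs, and shows the signal-peptide
coordinate arithmetic: curators store positions on the mature database
sequence, so a variant curated at position 409 on a protein with a
39-residue signal peptide is expected at position 370 in the cited
abstract (and 370 + 39 = 409 maps it back).
"""

from mutrel import adjust_position, parse_uniprot_variants

RECORD = """\
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
SQ   SEQUENCE   536 AA;  59700 MW;  ABCDEF1234567890 CRC64;
     MAAAA
//
"""


def main():
    records = parse_uniprot_variants(RECORD)
    print("Gold records (uniprot, wt, pos_db, pos_text_expected, mut, omim, pmid):")
    for r in records:
        print(f"  <{r.uniprot_id}, {r.wt}, {r.pos_db}, {r.pos_text_expected}, "
              f"{r.mut}, {r.omim_id}, {r.pmid}>")
    r = records[0]
    print(f"\nForward adjustment: {r.pos_text_expected} + 39 = "
          f"{adjust_position(r.pos_text_expected, 39)} (database space).")
    print("Matching accepts either coordinate space, so an extractor that")
    print("does not know the signal length still scores the variant.")


if __name__ == "__main__":
    main()
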