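"""Corpus-level orchestration: load a corpus, run a system variant over
every abstract, and score the output against gold."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import association, corpus_io, gold_eval
from .association import RELATION_TYPES, SYSTEMS, AssociationTuple
from .corpus_io import Document, LexiconSet
from .entity_layer import EntityMention
from .gold_eval import EvalResult, GoldRecord


@dataclass
class Corpus:
    documents: list[Document]
    mentions_by_pmid: dict[str, list[EntityMention]]
    parses: dict
    lexicons: LexiconSet
    gold: list[GoldRecord] = field(default_factory=list)

    def pmids(self) -> list[str]:
        return [d.pmid for d in self.documents]


def load_corpus(pubtator, conllu, lexicon_dir, gold=None) -> Corpus:
    pairs = corpus_io.read_pubtator(pubtator)
    parses = corpus_io.read_conllu(conllu) if conllu else {}
    lexicons = corpus_io.load_lexicons(lexicon_dir)
    gold_records = gold_eval.read_gold_tsv(gold) if gold else []
    return Corpus(
        documents=[doc for doc, _ in pairs],
        mentions_by_pmid={doc.pmid: mentions for doc, mentions in pairs},
        parses=parses,
        lexicons=lexicons,
        gold=gold_records,
    )


def extract_corpus(corpus: Corpus, system: str,
                   documents: list[Document] | None = None,
                   all_types: bool = False):
    """Run one system variant over the corpus.

    Returns the flat tuple list (ternary only), or with ``all_types`` a
    dict keyed by relation type including the binary records.
    """
    docs = corpus.documents if documents is None else documents
    if not all_types:
        out: list[AssociationTuple] = []
        for doc in docs:
            out.extend(association.run_variant(
                doc, corpus.parses, corpus.lexicons, system,
                mentions=corpus.mentions_by_pmid.get(doc.pmid)))
        return out
    by_type: dict[str, list[AssociationTuple]] = {t: [] for t in RELATION_TYPES}
    for doc in docs:
        result = association.run_variant_all_types(
            doc, corpus.parses, corpus.lexicons, system,
            mentions=corpus.mentions_by_pmid.get(doc.pmid))
        for t in RELATION_TYPES:
            by_type[t].extend(result[t])
    return by_type


def processed_mentions(corpus: Corpus) -> dict[str, list[EntityMention]]:
    """Merged mention lists per abstract (pattern + dictionary +
    supplied annotations), as used for filtering and error analysis."""
    out = {}
    for doc in corpus.documents:
        prepared = association.prepare_document(
            doc, corpus.parses, corpus.lexicons,
            mentions=corpus.mentions_by_pmid.get(doc.pmid))
        out[doc.pmid] = prepared.mentions
    return out


def evaluate_corpus(corpus: Corpus, systems=SYSTEMS,
                    relation_types=RELATION_TYPES,
                    documents: list[Document] | None = None) -> pd.DataFrame:
    """Precision/recall/F table: one row per system, one column block per
    relation type (the standard layout for comparing the variants)."""
    pmids = {d.pmid for d in (documents if documents is not None else corpus.documents)}
    gold = [g for g in corpus.gold if g.pmid in pmids]
    rows = []
    for system in systems:
        by_type = extract_corpus(corpus, system, documents=documents, all_types=True)
        row: dict = {"system": system}
        for rtype in relation_types:
            pool = by_type[rtype] + (by_type["PMD"] if rtype != "PMD" else [])
            res: EvalResult = gold_eval.score(pool, gold, rtype)
            row[f"{rtype}_P"] = round(res.precision, 1)
            row[f"{rtype}_R"] = round(res.recall, 1)
            row[f"{rtype}_F"] = round(res.f_measure, 1)
        rows.append(row)
    return pd.DataFrame(rows).set_index("system")


def write_tuples_tsv(tuples: list[AssociationTuple], path) -> None:
    """Output layout: pmid, uniprot, residues, both coordinate spaces,
    ';'-joined OMIM ids, derivation method and evidence sentences."""
    lines = ["pmid\tuniprot_id\twt\tpos_text\tpos_norm\tmut\tomim_ids\tmethod\tevidence"]
    for t in tuples:
        evidence = ";".join(str(k[1]) for k in t.evidence)
        lines.append("\t".join([
            t.pmid, t.uniprot_id or "", t.wt or "",
            str(t.pos_text or ""), str(t.pos_norm or ""), t.mut or "",
            ";".join(sorted(t.omim_ids)), t.method, evidence]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
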