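"""Gold-standard construction from curated variant records, corpus
filtering/splitting, scoring, and recall-error categorization.

The benchmark reference is not a text-annotated corpus but tuples
reconstructed from UniProtKB/SwissProt-style curated records: each
natural-variant feature with a disease cross-reference and a cited PMID
yields one gold record.  Curators report positions on the mature
database sequence; when the entry has a signal peptide the position
printed in the cited abstract is shorter by the signal length, so both
coordinate spaces are kept on the record and either is accepted when
matching system output.
"""

from __future__ import annotations

import csv
import io
import logging
import random
import re
from dataclasses import dataclass
from pathlib import Path

from Bio import SwissProt

from .association import RELATION_TYPES, AssociationTuple
from .corpus_io import DISEASE, MUTATION, PROTEIN
from .entity_layer import EntityMention, MutationTriple
from . import residues

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GoldRecord:
    """One curated variant-disease-citation tuple.

    ``pos_db`` is the UniProt (database-space) position;
    ``pos_text_expected`` the position expected in the cited abstract
    (``pos_db`` minus the signal-peptide length).  ``omim_id`` is None
    for variants curated without a disease link (protein-mutation gold
    only).
    """

    uniprot_id: str
    wt: str
    pos_db: int
    pos_text_expected: int
    mut: str
    omim_id: str | None
    pmid: str
    label: str = ""

    def __post_init__(self):
        if self.pos_text_expected < 1 or self.pos_db < self.pos_text_expected:
            raise ValueError("positions must satisfy 1 <= pos_text <= pos_db")


@dataclass(frozen=True)
class EvalResult:
    """Precision/recall/F for one relation type, in percent."""

    relation_type: str
    tp: float
    fp: float
    fn: float

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else 0.0

    @property
    def f_measure(self) -> float:
        return f_measure(self.precision, self.recall)

    @classmethod
    def from_counts(cls, tp, fp, fn, relation_type: str = "PMD") -> "EvalResult":
        return cls(relation_type, tp, fp, fn)


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# gold construction from curated flat-text records

_VARIANT_NOTE = re.compile(r"^([A-Z])\s*->\s*([A-Z])\s*(?:\((.*)\))?", re.DOTALL)
_DISEASE_COMMENT = re.compile(r"\(([^()]+)\)\s*\[MIM:(\d+)\]")
_PUBMED = re.compile(r"PubMed:(\d+)")


def parse_uniprot_variants(source) -> list[GoldRecord]:
    """Build gold records from SwissProt-style flat text.

    *source* may be a path or raw flat text.  For every VARIANT feature
    carrying a substitution note and cited PMIDs, one record is emitted
    per (disease OMIM id, PMID); variants without a disease cross-
    reference yield records with ``omim_id=None`` (they enter the
    protein-mutation gold only).  Variants lacking any PMID are skipped
    and counted in the log.
    """
    text = None
    if isinstance(source, (str, Path)):
        p = Path(source)
        if isinstance(source, Path) or ("\n" not in str(source) and p.exists()):
            text = p.read_text(encoding="utf-8")
        else:
            text = str(source)
    else:
        text = source.read()

    records: list[GoldRecord] = []
    skipped = 0
    for rec in SwissProt.parse(io.StringIO(text)):
        entry = rec.entry_name
        signal = 0
        disease_mims: dict[str, str] = {}
        for comment in rec.comments:
            if comment.startswith("DISEASE:"):
                for abbr, mim in _DISEASE_COMMENT.findall(comment):
                    disease_mims[abbr.strip()] = mim
        for feat in rec.features:
            if feat.type == "SIGNAL":
                try:
                    signal = int(feat.location.end)
                except (TypeError, ValueError):
                    signal = 0
        for feat in rec.features:
            if feat.type != "VARIANT":
                continue
            note = feat.qualifiers.get("note", "")
            m = _VARIANT_NOTE.match(note)
            if m is None:
                continue
            wt = residues.to_three(m.group(1))
            mut = residues.to_three(m.group(2))
            if wt is None or mut is None:
                continue
            pos_db = int(feat.location.end)
            pmids = _PUBMED.findall(feat.qualifiers.get("evidence", ""))
            if not pmids:
                skipped += 1
                continue
            context = m.group(3) or ""
            names = [re.sub(r"^in\s+", "", n.strip())
                     for n in re.split(r"[;,]| and ", context)]
            omims = sorted({disease_mims[n] for n in names if n in disease_mims})
            pos_text = pos_db - signal if pos_db - signal >= 1 else pos_db
            for pmid in pmids:
                if omims:
                    for omim in omims:
                        records.append(GoldRecord(entry, wt, pos_db, pos_text,
                                                  mut, omim, pmid))
                else:
                    records.append(GoldRecord(entry, wt, pos_db, pos_text,
                                              mut, None, pmid))
    if skipped:
        log.info("parse_uniprot_variants: %d variants without PMID skipped", skipped)
    return records


GOLD_COLUMNS = ("pmid", "uniprot_id", "wt", "pos_db", "pos_text", "mut",
                "omim_id", "label")


def write_gold_tsv(records: list[GoldRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(GOLD_COLUMNS)
        for r in records:
            writer.writerow([r.pmid, r.uniprot_id, r.wt, r.pos_db, r.pos_text_expected,
                             r.mut, r.omim_id or "", r.label])


def read_gold_tsv(path) -> list[GoldRecord]:
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(GoldRecord(
                uniprot_id=row["uniprot_id"], wt=row["wt"],
                pos_db=int(row["pos_db"]), pos_text_expected=int(row["pos_text"]),
                mut=row["mut"], omim_id=row["omim_id"] or None,
                pmid=row["pmid"], label=row.get("label", "")))
    return records


def tuples_from_gold(records: list[GoldRecord]) -> list[AssociationTuple]:
    """Project gold records onto the system tuple space (used for
    fixed-point checks and for building reference outputs)."""
    out = []
    for r in records:
        if r.omim_id is None:
            continue
        out.append(AssociationTuple(
            pmid=r.pmid, uniprot_id=r.uniprot_id, wt=r.wt,
            pos_text=r.pos_text_expected, pos_norm=r.pos_db, mut=r.mut,
            omim_ids=frozenset([r.omim_id]), method="gold"))
    return out


# ---------------------------------------------------------------------------
# corpus filter and split

def filter_corpus(docs_with_mentions):
    """Keep only abstracts mentioning at least one protein, one mutation
    and one disease."""
    kept = []
    for doc, mentions in docs_with_mentions:
        classes = {m.eclass for m in mentions}
        if {PROTEIN, MUTATION, DISEASE} <= classes:
            kept.append((doc, mentions))
    return kept


def split_corpus(items, dev_fraction: float = 0.8, seed: int = 0):
    """Deterministic random split into (development, test)."""
    if not 0 < dev_fraction < 1:
        raise ValueError("dev_fraction must lie strictly between 0 and 1")
    items = list(items)
    rng = random.Random(seed)
    order = list(range(len(items)))
    rng.shuffle(order)
    n_dev = round(len(items) * dev_fraction)
    dev = [items[i] for i in sorted(order[:n_dev])]
    test = [items[i] for i in sorted(order[n_dev:])]
    return dev, test


# ---------------------------------------------------------------------------
# scoring

def _position_matches(tup: AssociationTuple, gold: GoldRecord) -> bool:
    # either coordinate space is accepted, mirroring the curator's
    # signal-peptide adjustment
    return tup.pos_norm == gold.pos_db or tup.pos_text == gold.pos_text_expected


def _matches(tup: AssociationTuple, gold: GoldRecord, rtype: str) -> bool:
    if tup.pmid != gold.pmid:
        return False
    if rtype in ("PMD", "PM", "PD") and tup.uniprot_id != gold.uniprot_id:
        return False
    if rtype in ("PMD", "PM", "MD"):
        if tup.wt != gold.wt or tup.mut != gold.mut or not _position_matches(tup, gold):
            return False
    if rtype in ("PMD", "MD", "PD"):
        if gold.omim_id is None or gold.omim_id not in tup.omim_ids:
            return False
    return True


def _gold_key(g: GoldRecord, rtype: str) -> tuple:
    if rtype == "PMD":
        return (g.pmid, g.uniprot_id, g.wt, g.pos_db, g.mut, g.omim_id)
    if rtype == "PM":
        return (g.pmid, g.uniprot_id, g.wt, g.pos_db, g.mut)
    if rtype == "MD":
        return (g.pmid, g.wt, g.pos_db, g.mut, g.omim_id)
    if rtype == "PD":
        return (g.pmid, g.uniprot_id, g.omim_id)
    raise ValueError(f"unknown relation type {rtype!r}")


def _required_fields(tup: AssociationTuple, rtype: str) -> bool:
    has_p = tup.uniprot_id is not None
    has_m = tup.wt is not None
    has_d = bool(tup.omim_ids)
    need = {"PMD": (has_p, has_m, has_d), "PM": (has_p, has_m),
            "MD": (has_m, has_d), "PD": (has_p, has_d)}
    if rtype not in need:
        raise ValueError(f"unknown relation type {rtype!r}")
    return all(need[rtype])


def _sys_key(tup: AssociationTuple, rtype: str) -> tuple:
    if rtype == "PMD":
        return (tup.pmid, tup.uniprot_id, tup.wt, tup.pos_norm, tup.mut, tup.omim_ids)
    if rtype == "PM":
        return (tup.pmid, tup.uniprot_id, tup.wt, tup.pos_norm, tup.mut)
    if rtype == "MD":
        return (tup.pmid, tup.wt, tup.pos_norm, tup.mut, tup.omim_ids)
    if rtype == "PD":
        return (tup.pmid, tup.uniprot_id, tup.omim_ids)
    raise ValueError(f"unknown relation type {rtype!r}")


def score(system_tuples: list[AssociationTuple], gold: list[GoldRecord],
          rtype: str) -> EvalResult:
    """Match system output against gold and count TP/FP/FN.

    Matching for the ternary type requires the same PMID, UniProt id,
    residues, a position agreeing in either coordinate space, and a
    non-empty intersection between the system's retained OMIM ids and the
    gold OMIM id; binary types use the corresponding field subsets.
    System tuples missing a required field for *rtype* are ignored;
    disease-less gold records only participate in the PM gold.
    """
    if rtype not in RELATION_TYPES:
        raise ValueError(f"unknown relation type {rtype!r}")
    gold_pool: dict[tuple, GoldRecord] = {}
    for g in gold:
        if rtype != "PM" and g.omim_id is None:
            continue
        gold_pool.setdefault(_gold_key(g, rtype), g)
    sys_pool: dict[tuple, AssociationTuple] = {}
    for t in system_tuples:
        if _required_fields(t, rtype):
            sys_pool.setdefault(_sys_key(t, rtype), t)

    matched_gold: set[tuple] = set()
    tp = fp = 0
    for t in sys_pool.values():
        hits = [k for k, g in gold_pool.items() if _matches(t, g, rtype)]
        if hits:
            tp += 1
            matched_gold.update(hits)
        else:
            fp += 1
    fn = len(gold_pool) - len(matched_gold)
    return EvalResult(rtype, tp, fp, fn)


# ---------------------------------------------------------------------------
# recall-error categorization

ENTITY_ABSENT = "ENTITY_ABSENT"
EXTRACTION_MISS = "EXTRACTION_MISS"


@dataclass(frozen=True)
class ErrorCategory:
    kind: str                 # ENTITY_ABSENT or EXTRACTION_MISS
    missing: str | None = None  # entity class absent from the abstract


def categorize_recall_errors(fn_gold: list[GoldRecord],
                             mentions_by_pmid: dict[str, list[EntityMention]],
                             lexicons) -> dict[GoldRecord, ErrorCategory]:
    """Separate recall errors into entity-absence vs extraction misses.

    A gold record is an ENTITY_ABSENT error when the abstract contains no
    mention of the gold protein (by normalized id), of the gold variant
    (triple in either coordinate space) or of the gold disease (by mapped
    OMIM id); otherwise the entities were present and the miss is the
    extractor's (EXTRACTION_MISS).
    """
    out: dict[GoldRecord, ErrorCategory] = {}
    for g in fn_gold:
        mentions = mentions_by_pmid.get(g.pmid, [])
        protein_present = False
        mutation_present = False
        disease_present = g.omim_id is None
        for m in mentions:
            if m.eclass == PROTEIN:
                mnems = set(m.ids) | {
                    lexicons.entrez_to_mnemonic.get(i) for i in m.ids}
                if g.uniprot_id in mnems:
                    protein_present = True
            elif m.eclass == MUTATION and m.mutation is not None:
                t = m.mutation
                if (t.wt, t.mut) == (g.wt, g.mut) and t.pos in (g.pos_db, g.pos_text_expected):
                    mutation_present = True
            elif m.eclass == DISEASE and g.omim_id is not None:
                for i in m.ids:
                    mesh = i.removeprefix("MESH:")
                    if g.omim_id in lexicons.omim_for_mesh(mesh):
                        disease_present = True
        for cls, present in ((PROTEIN, protein_present), (MUTATION, mutation_present),
                             (DISEASE, disease_present)):
            if not present:
                out[g] = ErrorCategory(ENTITY_ABSENT, cls.lower())
                break
        else:
            out[g] = ErrorCategory(EXTRACTION_MISS)
    return out
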