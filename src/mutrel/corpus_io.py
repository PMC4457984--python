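"""Readers/writers for corpus formats and lexicon resources.

Formats handled here:

* PubTator pipe/tab files (title, abstract and entity annotation lines),
* CoNLL-U dependency parses, one block per sentence, keyed by
  ``# pmid`` / ``# sent_id`` comments,
* BRAT standoff ``.ann`` output,
* plain-TSV lexicons (protein names, disease names, MeSH->OMIM map,
  signal-peptide lengths, trigger words).

Document offsets follow the PubTator convention: 0-based, half-open,
computed over ``title + single space + abstract``. The title is treated
as sentence 0.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

log = logging.getLogger(__name__)

PROTEIN = "PROTEIN"
DISEASE = "DISEASE"
MUTATION = "MUTATION"

#: PubTator annotation type -> internal entity class; anything else is skipped
PUBTATOR_TYPES = {
    "Gene": PROTEIN,
    "Protein": PROTEIN,
    "Disease": DISEASE,
    "Mutation": MUTATION,
    "ProteinMutation": MUTATION,
}

#: built-in trigger lexicon used when no triggers file is supplied.
#: Trigger nouns act as anaphoric references to entities of the mapped
#: class in neighbouring sentences.
DEFAULT_TRIGGERS: dict[str, str] = {
    "mutation": MUTATION,
    "mutations": MUTATION,
    "mutant": MUTATION,
    "mutants": MUTATION,
    "mutational": MUTATION,
    "variation": MUTATION,
    "variations": MUTATION,
    "variant": MUTATION,
    "variants": MUTATION,
    "patient": DISEASE,
    "patients": DISEASE,
    "phenotype": DISEASE,
    "phenotypes": DISEASE,
}


# ---------------------------------------------------------------------------
# documents and sentences

@dataclass(frozen=True)
class Sentence:
    """A sentence with its [start, end) character span in the document."""

    index: int
    text: str
    start: int
    end: int


@dataclass
class Document:
    pmid: str
    title: str
    abstract: str
    sentences: list[Sentence] = field(default_factory=list)

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}" if self.abstract else self.title

    @classmethod
    def build(cls, pmid: str, title: str, abstract: str) -> "Document":
        doc = cls(pmid=pmid, title=title, abstract=abstract)
        sentences: list[Sentence] = []
        if title:
            sentences.append(Sentence(0, title, 0, len(title)))
        offset = len(title) + 1
        for s, e in split_sentences(abstract):
            sentences.append(
                Sentence(len(sentences), abstract[s:e], s + offset, e + offset)
            )
        doc.sentences = sentences
        return doc

    def find_sentence(self, start: int, end: int) -> Sentence | None:
        """Sentence fully containing the document span, or None."""
        for sent in self.sentences:
            if sent.start <= start and end <= sent.end:
                return sent
        return None

    def to_document_span(self, sentence_index: int, start: int, end: int) -> tuple[int, int]:
        sent = self.sentences[sentence_index]
        return sent.start + start, sent.start + end


_TERMINAL = ".!?"


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Rule-based sentence spans over *text* (0-based, half-open).

    Splits after sentence-final punctuation followed by whitespace and an
    upper-case letter or digit.  Never splits inside parentheses or
    brackets, which protects mentions like "(Ser169Pro)".
    """
    spans: list[tuple[int, int]] = []
    depth = 0
    start = 0
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch in "([{":
            depth += 1
        elif ch in ")]}":
            depth = max(0, depth - 1)
        elif ch in _TERMINAL and depth == 0:
            j = i + 1
            while j < n and text[j] in _TERMINAL:
                j += 1
            k = j
            while k < n and text[k].isspace():
                k += 1
            if k < n and k > j and (text[k].isupper() or text[k].isdigit()):
                spans.append((start, j))
                start = k
                i = k
                continue
            i = j
            continue
        i += 1
    if start < n and text[start:].strip():
        spans.append((start, n))
    return spans


# ---------------------------------------------------------------------------
# PubTator

def read_pubtator(path) -> list[tuple[Document, list]]:
    """Parse a PubTator pipe/tab file.

    Returns one ``(Document, mentions)`` pair per abstract.  Annotation
    offsets are document-level and are converted to (sentence index,
    in-sentence span); lines whose span text does not match the document
    text are rejected and logged.  Unknown annotation types (Species,
    Chemical, ...) are skipped with a warning.
    """
    from .entity_layer import EntityMention, parse_mutation_string

    blocks: list[list[str]] = [[]]
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if raw.strip():
            blocks[-1].append(raw)
        elif blocks[-1]:
            blocks.append([])
    if blocks and not blocks[-1]:
        blocks.pop()

    out: list[tuple[Document, list]] = []
    for block in blocks:
        title = abstract = None
        pmid = None
        ann_lines: list[list[str]] = []
        for line in block:
            m = re.match(r"^([^|\t]+)\|t\|(.*)$", line)
            if m:
                pmid, title = m.group(1), m.group(2)
                continue
            m = re.match(r"^([^|\t]+)\|a\|(.*)$", line)
            if m:
                abstract = m.group(2)
                continue
            parts = line.split("\t")
            if len(parts) >= 5:
                ann_lines.append(parts)
        if pmid is None or title is None:
            raise ValueError(f"PubTator block without a title line: {block[:1]}")
        if abstract is None:
            raise ValueError(f"PubTator document {pmid} lacks an abstract line")
        doc = Document.build(pmid, title, abstract)
        mentions = []
        for parts in ann_lines:
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                log.warning("pmid %s: malformed offsets in %r", pmid, parts)
                continue
            surface, ann_type = parts[3], parts[4]
            norm_id = parts[5] if len(parts) > 5 else ""
            if doc.text[start:end] != surface:
                log.warning(
                    "pmid %s: span [%d,%d) reads %r, annotation says %r; dropped",
                    pmid, start, end, doc.text[start:end], surface,
                )
                continue
            eclass = PUBTATOR_TYPES.get(ann_type)
            if eclass is None:
                log.warning("pmid %s: unknown annotation type %r skipped", pmid, ann_type)
                continue
            sent = doc.find_sentence(start, end)
            if sent is None:
                log.warning("pmid %s: annotation [%d,%d) crosses sentence bounds; dropped",
                            pmid, start, end)
                continue
            triple = None
            if eclass == MUTATION:
                triple = parse_mutation_string(surface) or parse_mutation_string(norm_id)
                if triple is None:
                    log.warning("pmid %s: mutation %r not parseable as a substitution; dropped",
                                pmid, surface)
                    continue
            ids = tuple(i for i in (norm_id,) if i and eclass != MUTATION)
            mentions.append(EntityMention(
                pmid=pmid,
                sentence_index=sent.index,
                start=start - sent.start,
                end=end - sent.start,
                surface=surface,
                eclass=eclass,
                ids=ids,
                mutation=triple,
                source="pubtator",
            ))
        out.append((doc, mentions))
    return out


def write_pubtator(pairs, path) -> None:
    """Inverse of :func:`read_pubtator` (used for round-trip checks)."""
    lines: list[str] = []
    reverse_types = {PROTEIN: "Gene", DISEASE: "Disease", MUTATION: "Mutation"}
    for doc, mentions in pairs:
        lines.append(f"{doc.pmid}|t|{doc.title}")
        lines.append(f"{doc.pmid}|a|{doc.abstract}")
        for m in sorted(mentions, key=lambda m: (m.sentence_index, m.start)):
            s, e = doc.to_document_span(m.sentence_index, m.start, m.end)
            norm = m.ids[0] if m.ids else (m.mutation.short() if m.mutation else "")
            lines.append("\t".join(
                [doc.pmid, str(s), str(e), m.surface, reverse_types[m.eclass], norm]))
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# CoNLL-U

def read_conllu(path) -> dict:
    """Read per-sentence dependency parses.

    Returns a map ``(pmid, sentence_index) -> DependencyGraph``.  The
    HEAD/DEPREL columns become edges; the enhanced-dependencies column
    (DEPS), when present, supplies the collapsed-preposition /
    propagated-conjunction edges.  Blocks whose HEAD indices exceed the
    token count are skipped with a log message.
    """
    from .relation_graph import DependencyGraph

    graphs: dict = {}
    block: list[str] = []

    def flush(block: list[str]) -> None:
        if not block:
            return
        pmid = sent_id = None
        rows = []
        for line in block:
            if line.startswith("#"):
                m = re.match(r"#\s*pmid\s*=?\s*(\S+)", line)
                if m:
                    pmid = m.group(1)
                m = re.match(r"#\s*sent_id\s*=?\s*(\S+)", line)
                if m:
                    sent_id = m.group(1)
                continue
            cols = line.split("\t")
            if "-" in cols[0] or "." in cols[0]:
                continue  # multiword/empty tokens not used
            rows.append(cols)
        if pmid is None or sent_id is None or not rows:
            return
        key = (pmid, int(sent_id))
        n = len(rows)
        try:
            heads = [int(c[6]) for c in rows]
        except (ValueError, IndexError):
            log.warning("%s: unparsable HEAD column; sentence skipped", key)
            return
        if any(h < 0 or h > n for h in heads):
            log.warning("%s: HEAD index exceeds token count; sentence skipped", key)
            return
        g = DependencyGraph(key, {i + 1: c[1] for i, c in enumerate(rows)},
                            lemmas={i + 1: c[2] for i, c in enumerate(rows)})
        for i, cols in enumerate(rows):
            head = heads[i]
            if head > 0:
                g.add_edge(head, i + 1, cols[7])
            deps = cols[8] if len(cols) > 8 else "_"
            if deps and deps != "_":
                for item in deps.split("|"):
                    h, _, rel = item.partition(":")
                    try:
                        h = int(h)
                    except ValueError:
                        continue
                    if 1 <= h <= n:
                        g.add_edge(h, i + 1, rel)
        graphs[key] = g

    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if raw.strip():
            block.append(raw)
        else:
            flush(block)
            block = []
    flush(block)
    return graphs


# ---------------------------------------------------------------------------
# BRAT standoff

_BRAT_LABEL = {PROTEIN: "Protein", DISEASE: "Disease", MUTATION: "Mutation"}


def write_brat(doc: Document, mentions, relations, path, write_text: bool = True) -> None:
    """Write mentions and relations as BRAT standoff.

    *relations* is an iterable of tuples of mention indices (2 -> ``R``
    relation line, 3 -> ``E`` event line whose trigger is the first
    argument).  Reading the written file recovers identical spans and
    relation argument sets (:func:`read_brat`).
    """
    path = Path(path)
    lines: list[str] = []
    for i, m in enumerate(mentions):
        s, e = doc.to_document_span(m.sentence_index, m.start, m.end)
        lines.append(f"T{i + 1}\t{_BRAT_LABEL[m.eclass]} {s} {e}\t{doc.text[s:e]}")
    r = e = 0
    for members in relations:
        tids = [f"T{i + 1}" for i in members]
        roles = [_BRAT_LABEL[mentions[i].eclass] for i in members]
        if len(members) == 2:
            r += 1
            lines.append(f"R{r}\tAssociation Arg1:{tids[0]} Arg2:{tids[1]}")
        elif len(members) == 3:
            e += 1
            args = " ".join(f"{role}:{tid}" for role, tid in zip(roles, tids))
            lines.append(f"E{e}\tAssociation:{tids[0]} {args}")
        else:
            raise ValueError(f"relation arity {len(members)} not supported")
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    if write_text:
        path.with_suffix(".txt").write_text(doc.text, encoding="utf-8")


def read_brat(path):
    """Read a ``.ann`` file back: (spans ``Tid -> (label, start, end, text)``,
    relations as list of frozensets of T ids)."""
    spans: dict[str, tuple[str, int, int, str]] = {}
    relations: list[frozenset[str]] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        tag, _, rest = line.partition("\t")
        if tag.startswith("T"):
            head, _, surface = rest.partition("\t")
            label, s, e = head.split(" ")
            if tag in spans:
                raise ValueError(f"duplicate BRAT id {tag}")
            spans[tag] = (label, int(s), int(e), surface)
        elif tag.startswith("R"):
            parts = rest.split()
            relations.append(frozenset(p.split(":")[1] for p in parts[1:]))
        elif tag.startswith("E"):
            parts = rest.split()
            relations.append(frozenset(p.split(":", 1)[1] for p in parts[1:]))
    return spans, relations


# ---------------------------------------------------------------------------
# lexicons

def normalize_term(term: str) -> str:
    """Lexical normalization used for all dictionary keys: case folding,
    punctuation stripped to spaces, whitespace collapsed."""
    term = term.casefold()
    term = re.sub(r"[^\w\s]|_", " ", term)
    return " ".join(term.split())


@dataclass
class LexiconSet:
    """Bundled terminology resources.

    ``protein_names``: normalized name -> (uniprot_mnemonic, entrez_id);
    ``disease_names``: normalized name -> MeSH id;
    ``mesh_to_omim``: MeSH id -> non-empty set of OMIM ids;
    ``signal_lengths``: UniProt mnemonic -> signal-peptide length (>= 0);
    ``triggers``: trigger word -> entity class it refers to.
    """

    protein_names: dict[str, tuple[str, str]] = field(default_factory=dict)
    disease_names: dict[str, str] = field(default_factory=dict)
    mesh_to_omim: dict[str, frozenset[str]] = field(default_factory=dict)
    signal_lengths: dict[str, int] = field(default_factory=dict)
    triggers: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TRIGGERS))
    entrez_to_mnemonic: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for length in self.signal_lengths.values():
            if length < 0:
                raise ValueError("signal-peptide lengths must be non-negative")
        for mesh, omims in self.mesh_to_omim.items():
            if not omims:
                raise ValueError(f"mesh_to_omim[{mesh}] is empty")
        if not self.entrez_to_mnemonic:
            self.entrez_to_mnemonic = {
                entrez: mnem for mnem, entrez in self.protein_names.values() if entrez
            }

    def lookup_protein(self, name: str):
        return self.protein_names.get(normalize_term(name))

    def lookup_disease(self, name: str):
        return self.disease_names.get(normalize_term(name))

    def omim_for_mesh(self, mesh_id: str) -> frozenset[str]:
        return self.mesh_to_omim.get(mesh_id, frozenset())

    def trigger_class(self, word: str) -> str | None:
        w = word.lower()
        if w in self.triggers:
            return self.triggers[w]
        if w.endswith("s") and w[:-1] in self.triggers:
            return self.triggers[w[:-1]]
        return None


def _read_tsv(path: Path) -> list[list[str]]:
    rows = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rows.append(line.rstrip("\n").split("\t"))
    return rows


REQUIRED_LEXICONS = ("proteins.tsv", "diseases.tsv", "mesh_omim.tsv", "signal_peptides.tsv")


def load_lexicons(directory) -> LexiconSet:
    """Load a lexicon directory into a :class:`LexiconSet`.

    Required files: ``proteins.tsv`` (name, mnemonic, entrez),
    ``diseases.tsv`` (name, mesh), ``mesh_omim.tsv`` (mesh, omim — one row
    per pair), ``signal_peptides.tsv`` (mnemonic, length).  Optional:
    ``triggers.tsv`` (word, class); when missing or empty the built-in
    trigger list is used.  Keys are case-insensitive and
    punctuation-normalized.
    """
    directory = Path(directory)
    for name in REQUIRED_LEXICONS:
        if not (directory / name).exists():
            raise FileNotFoundError(f"required lexicon file missing: {directory / name}")

    proteins: dict[str, tuple[str, str]] = {}
    for row in _read_tsv(directory / "proteins.tsv"):
        if row and row[0].lower() == "name":
            continue
        name, mnem = row[0], row[1]
        entrez = row[2] if len(row) > 2 else ""
        proteins[normalize_term(name)] = (mnem, entrez)

    diseases: dict[str, str] = {}
    for row in _read_tsv(directory / "diseases.tsv"):
        if row and row[0].lower() == "name":
            continue
        diseases[normalize_term(row[0])] = row[1]

    mesh_omim: dict[str, set[str]] = {}
    for row in _read_tsv(directory / "mesh_omim.tsv"):
        if row and row[0].lower() in ("mesh", "mesh_id"):
            continue
        mesh_omim.setdefault(row[0], set()).add(row[1])

    signals: dict[str, int] = {}
    for row in _read_tsv(directory / "signal_peptides.tsv"):
        if row and row[0].lower() in ("uniprot", "mnemonic"):
            continue
        signals[row[0]] = int(row[1])

    triggers = dict(DEFAULT_TRIGGERS)
    trig_path = directory / "triggers.tsv"
    if trig_path.exists():
        rows = [r for r in _read_tsv(trig_path) if r and r[0].lower() != "word"]
        if rows:
            triggers = {r[0].lower(): r[1].upper() for r in rows}

    return LexiconSet(
        protein_names=proteins,
        disease_names=diseases,
        mesh_to_omim={k: frozenset(v) for k, v in mesh_omim.items()},
        signal_lengths=signals,
        triggers=triggers,
    )
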