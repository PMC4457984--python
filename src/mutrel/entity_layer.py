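"""Entity detection and normalization.

Four concerns live here:

* a regular-expression grammar for point-substitution mentions
  (``R203C``, ``Ser169Pro``, ``aspartate 399 to asparagine``, arrow and
  ``p.`` spellings), each normalized to a wild-type / position / mutant
  residue triple;
* longest-match dictionary tagging of protein and disease names against
  the bundled lexicons;
* abbreviation detection (Schwartz-style parenthesis matching) that
  propagates the long form's class and ids to short-form occurrences
  across the abstract;
* merging of mentions from several annotators, collapsing overlapping
  same-class spans to the longest one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources as importlib_resources
from typing import TYPE_CHECKING

from . import residues
from .corpus_io import DISEASE, MUTATION, PROTEIN, Sentence, normalize_term

if TYPE_CHECKING:  # pragma: no cover
    from .corpus_io import Document, LexiconSet


@dataclass(frozen=True)
class MutationTriple:
    """A single amino-acid substitution in text coordinates.

    ``wt`` and ``mut`` are 3-letter residue codes; ``pos`` is the
    (1-based) residue position as printed in the text, i.e. before any
    signal-peptide adjustment.
    """

    wt: str
    pos: int
    mut: str

    def __post_init__(self):
        if self.wt not in residues.THREE_LETTER_CODES:
            raise ValueError(f"unknown residue code {self.wt!r}")
        if self.mut not in residues.THREE_LETTER_CODES:
            raise ValueError(f"unknown residue code {self.mut!r}")
        if self.pos < 1:
            raise ValueError("residue positions are 1-based")

    def short(self) -> str:
        """1-letter serialization, e.g. ``V617F``."""
        return f"{residues.THREE_TO_ONE[self.wt]}{self.pos}{residues.THREE_TO_ONE[self.mut]}"


@dataclass
class EntityMention:
    """A typed, normalized span inside one sentence.

    ``start``/``end`` are 0-based half-open offsets into the sentence
    text.  ``ids`` carries normalized identifiers (UniProt mnemonic
    and/or Entrez id for proteins, MeSH id for diseases); MUTATION
    mentions always carry a :class:`MutationTriple`.  ``token`` is filled
    by the placeholder-substitution stage.
    """

    pmid: str
    sentence_index: int
    start: int
    end: int
    surface: str
    eclass: str
    ids: tuple[str, ...] = ()
    mutation: MutationTriple | None = None
    source: str = ""
    token: str | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("mention span is empty")
        if self.eclass == MUTATION and self.mutation is None:
            raise ValueError("MUTATION mentions must carry a MutationTriple")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# substitution grammar

_AA1 = "|".join(sorted(residues.ONE_TO_THREE))
_AA3 = "|".join(sorted(residues.THREE_TO_ONE))
_AAFULL = "|".join(sorted(residues.FULL_TO_THREE, key=len, reverse=True)).replace(" ", r"\s+")
_AAW = f"{_AA3}|{_AAFULL}"


def _load_patterns():
    text = (importlib_resources.files("mutrel") / "resources" / "mutation_patterns.tsv").read_text()
    patterns = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, flags, pattern = line.split("\t")
        pattern = (pattern.replace("{AA1}", _AA1)
                          .replace("{AA3}", _AA3)
                          .replace("{AAW}", _AAW))
        re_flags = re.IGNORECASE if "I" in flags else 0
        patterns.append((name, "X" in flags, re.compile(pattern, re_flags)))
    return patterns


_PATTERNS = _load_patterns()


def parse_mutation_string(text: str) -> MutationTriple | None:
    """Parse a bare mutation string (e.g. ``p.V617F``, ``Ser169Pro``)."""
    if not text:
        return None
    for _, extended, pat in _PATTERNS:
        if extended:
            continue
        m = pat.fullmatch(text.strip())
        if m:
            return _triple_from_match(m)
    return None


def _triple_from_match(m: re.Match) -> MutationTriple | None:
    wt = residues.to_three(re.sub(r"[\s-]+", " ", m.group("wt")))
    mut = residues.to_three(re.sub(r"[\s-]+", " ", m.group("mut")))
    if wt is None or mut is None:
        return None
    return MutationTriple(wt=wt, pos=int(m.group("pos")), mut=mut)


def detect_mutations(sentence: Sentence | str, *, pmid: str = "",
                     sentence_index: int | None = None,
                     extended: bool = False) -> list[EntityMention]:
    """Find point-substitution mentions in one sentence.

    Overlapping matches are resolved to the longest span.  The optional
    extended grammar adds codon-level spellings ("codon 444, Leu (CTG) to
    Pro (CCG)"), which are off by default: the standard grammar is known
    not to cover them.
    """
    if isinstance(sentence, Sentence):
        text = sentence.text
        index = sentence.index if sentence_index is None else sentence_index
    else:
        text = sentence
        index = sentence_index or 0

    candidates = []
    for order, (name, is_ext, pat) in enumerate(_PATTERNS):
        if is_ext and not extended:
            continue
        for m in pat.finditer(text):
            triple = _triple_from_match(m)
            if triple is None:
                continue
            candidates.append((m.start(), m.end(), order, triple))

    # longest-match overlap resolution
    chosen: list[tuple[int, int, int, MutationTriple]] = []
    for cand in sorted(candidates, key=lambda c: (-(c[1] - c[0]), c[0], c[2])):
        if all(cand[1] <= s or cand[0] >= e for s, e, _, _ in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda c: c[0])

    return [
        EntityMention(
            pmid=pmid, sentence_index=index, start=s, end=e,
            surface=text[s:e], eclass=MUTATION, mutation=triple,
            source="pattern",
        )
        for s, e, _, triple in chosen
    ]


# ---------------------------------------------------------------------------
# dictionary tagging

_TOKEN_RE = re.compile(r"\w+")


def tag_dictionary(sentence: Sentence | str, lexicons: "LexiconSet", eclass: str, *,
                   pmid: str = "", sentence_index: int | None = None) -> list[EntityMention]:
    """Longest-match, case-insensitive dictionary lookup over token
    boundaries, for PROTEIN or DISEASE.  Matched names get their lexicon
    ids (UniProt mnemonic + Entrez for proteins, MeSH for diseases)."""
    if isinstance(sentence, Sentence):
        text = sentence.text
        index = sentence.index if sentence_index is None else sentence_index
    else:
        text = sentence
        index = sentence_index or 0

    if eclass == PROTEIN:
        table = lexicons.protein_names
    elif eclass == DISEASE:
        table = lexicons.disease_names
    else:
        raise ValueError(f"dictionary tagging handles PROTEIN/DISEASE, not {eclass}")
    if not table:
        return []
    max_words = max(len(key.split()) for key in table)

    tokens = list(_TOKEN_RE.finditer(text))
    mentions: list[EntityMention] = []
    i = 0
    while i < len(tokens):
        hit = None
        for width in range(min(max_words, len(tokens) - i), 0, -1):
            s, e = tokens[i].start(), tokens[i + width - 1].end()
            key = normalize_term(text[s:e])
            if key in table:
                hit = (s, e, table[key], width)
                break
        if hit is None:
            i += 1
            continue
        s, e, value, width = hit
        if eclass == PROTEIN:
            ids = tuple(v for v in value if v)
        else:
            ids = (value,)
        mentions.append(EntityMention(
            pmid=pmid, sentence_index=index, start=s, end=e,
            surface=text[s:e], eclass=eclass, ids=ids, source="dict",
        ))
        i += width
    return mentions


# ---------------------------------------------------------------------------
# abbreviation detection

_PAREN_RE = re.compile(r"\(([^()]{1,10})\)")


def _best_long_form_start(short: str, candidate: str) -> int | None:
    """Start offset of the long form inside *candidate*, by right-to-left
    greedy character matching: every short-form character must occur in
    the long form in order, and the first one must start a word."""
    s = len(short) - 1
    pos = len(candidate) - 1
    while s >= 0:
        ch = short[s].lower()
        if not ch.isalnum():
            s -= 1
            continue
        while pos >= 0 and (candidate[pos].lower() != ch or
                            (s == 0 and pos > 0 and candidate[pos - 1].isalnum())):
            pos -= 1
        if pos < 0:
            return None
        s -= 1
        pos -= 1
    return pos + 1


def detect_abbreviations(doc: "Document", mentions: list[EntityMention]) -> list[tuple[str, str]]:
    """Detect (short form, long form) abbreviation pairs in the document.

    When the long form overlaps an already-tagged PROTEIN or DISEASE
    mention, every other occurrence of the short form in the abstract is
    appended to *mentions* with the long form's class and ids.
    """
    text = doc.text
    pairs: list[tuple[str, str]] = []
    new: list[EntityMention] = []
    doc_spans = [
        (i, *doc.to_document_span(m.sentence_index, m.start, m.end))
        for i, m in enumerate(mentions)
    ]
    for pm in _PAREN_RE.finditer(text):
        short = pm.group(1).strip()
        if not (2 <= len(short) <= 10) or not any(c.isalpha() for c in short):
            continue
        if not short[0].isalnum():
            continue
        sent = doc.find_sentence(pm.start(), pm.start() + 1)
        window_floor = sent.start if sent is not None else 0
        prefix = text[:pm.start()]
        words = [(w.start(), w.end()) for w in re.finditer(r"\S+", prefix)
                 if w.start() >= window_floor]
        # candidate window bounded by min(|SF|+5, |SF|*2) words
        max_words = min(len(short) + 5, len(short) * 2)
        words = words[-max_words:]
        if not words:
            continue
        candidate = prefix[words[0][0]:words[-1][1]]
        offset = _best_long_form_start(short, candidate)
        if offset is None:
            continue
        long_start, long_end = words[0][0] + offset, words[-1][1]
        long_form = text[long_start:long_end]
        pairs.append((short, long_form))

        template = None
        for idx, ms, me in doc_spans:
            if ms < long_end and long_start < me:
                cand = mentions[idx]
                if cand.eclass in (PROTEIN, DISEASE):
                    template = cand
                    break
        if template is None:
            continue
        existing = {(s, e) for _, s, e in doc_spans}
        for occ in re.finditer(rf"(?<!\w){re.escape(short)}(?!\w)", text):
            if (occ.start(), occ.end()) in existing:
                continue
            sent = doc.find_sentence(occ.start(), occ.end())
            if sent is None:
                continue
            new.append(EntityMention(
                pmid=doc.pmid, sentence_index=sent.index,
                start=occ.start() - sent.start, end=occ.end() - sent.start,
                surface=short, eclass=template.eclass, ids=template.ids,
                source="abbrev",
            ))
    mentions.extend(new)
    return pairs


# ---------------------------------------------------------------------------
# merging

_CLASS_PRIORITY = {MUTATION: 0, PROTEIN: 1, DISEASE: 2}


def merge_mentions(*mention_lists) -> list[EntityMention]:
    """Consolidate mentions from several annotators.

    Overlapping same-class mentions in the same sentence collapse to the
    longest span with the union of contributing ids.  Mentions of
    different classes with identical spans keep only the highest-priority
    class (MUTATION > PROTEIN > DISEASE); other cross-class overlaps keep
    both.  Idempotent.
    """
    pool: list[EntityMention] = [m for lst in mention_lists for m in lst]
    merged: list[EntityMention] = []
    by_group: dict[tuple[int, str], list[EntityMention]] = {}
    for m in pool:
        by_group.setdefault((m.sentence_index, m.eclass), []).append(m)

    for (_, _), group in sorted(by_group.items()):
        group.sort(key=lambda m: (m.start, -(m.end - m.start)))
        clusters: list[list[EntityMention]] = []
        for m in group:
            if clusters and m.start < max(x.end for x in clusters[-1]):
                clusters[-1].append(m)
            else:
                clusters.append([m])
        for cluster in clusters:
            best = max(cluster, key=lambda m: (m.end - m.start, -m.start))
            ids = tuple(dict.fromkeys(i for m in cluster for i in m.ids))
            sources = ",".join(sorted({m.source for m in cluster if m.source}))
            mutation = best.mutation or next(
                (m.mutation for m in cluster if m.mutation), None)
            merged.append(replace(best, ids=ids, source=sources, mutation=mutation))

    # identical-span cross-class conflicts: keep the highest-priority class
    by_span: dict[tuple[str, int, int, int], list[EntityMention]] = {}
    for m in merged:
        by_span.setdefault((m.pmid, m.sentence_index, m.start, m.end), []).append(m)
    out: list[EntityMention] = []
    for _, group in sorted(by_span.items()):
        if len(group) > 1:
            group.sort(key=lambda m: _CLASS_PRIORITY[m.eclass])
            out.append(group[0])
        else:
            out.append(group[0])
    out.sort(key=lambda m: (m.sentence_index, m.start, _CLASS_PRIORITY[m.eclass]))
    return out
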