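"""Synthetic annotated corpora with controllable discourse structure.

Every stage of the pipeline is testable offline: the generator emits a
PubTator file, matching CoNLL-U parses of the *simplified* sentences
(placeholder tokens in place of entity mentions), a lexicon directory
and a gold TSV.  Documents come in five discourse classes:

* ``single_sentence`` — protein, mutation and disease share a sentence
  (apposition shape); recoverable from sentence co-occurrence upward;
* ``entity_link`` — disease and protein in one sentence ("caused by"
  shape), protein and mutation in another: only identity linking (S4)
  recovers the triple;
* ``trigger_link`` — a trigger headline ("Mutational spectrum analysis
  of ...") with the disease, protein and mutation in a later sentence:
  only trigger linking (S5) recovers it;
* ``entity_absent`` — four variants and the disease are mentioned but
  the gold protein never is: no variant can recover the gold
  (UNRECOVERABLE), emulating the dominant recall-error regime;
* distractors — all three classes present but never associated in gold.

Parses are built from per-template dependency trees (including
propagated-conjunction enhanced edges), so no live parser is needed, and
two runs with equal seeds produce byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

from . import residues
from .corpus_io import DEFAULT_TRIGGERS

_AA = sorted(residues.THREE_TO_ONE)

# no space before these tokens, no space after "("
_NO_SPACE_BEFORE = {".", ",", ")", ";", ":", "%"}


@dataclass
class CorpusSpec:
    """Knobs for the generator.

    The default mixture mirrors the discourse statistics the pipeline is
    meant to face: roughly a third of gold triples fully within one
    sentence, the rest split across sentences (recoverable via a shared
    entity or only via a trigger word), plus a slice of abstracts where
    the gold protein is never mentioned (the dominant recall-error
    cause), and distractor documents carrying no gold triple.
    """

    n_docs: int = 50
    frac_single_sentence: float = 0.36
    frac_entity_link: float = 0.25
    frac_trigger_link: float = 0.15
    frac_entity_absent: float = 0.15
    seed: int = 0
    signal_pool: tuple[int, ...] = (0, 0, 0, 19, 24, 39, 72)

    def __post_init__(self):
        total = (self.frac_single_sentence + self.frac_entity_link
                 + self.frac_trigger_link + self.frac_entity_absent)
        if total > 1.0 + 1e-9:
            raise ValueError("discourse-class fractions must sum to at most 1")
        for f in (self.frac_single_sentence, self.frac_entity_link,
                  self.frac_trigger_link, self.frac_entity_absent):
            if f < 0:
                raise ValueError("fractions must be non-negative")


class CorpusPaths(NamedTuple):
    pubtator: Path
    conllu: Path
    lexicon_dir: Path
    gold: Path


@dataclass
class _Protein:
    name: str
    mnemonic: str
    entrez: str
    signal: int


@dataclass
class _Disease:
    name: str
    mesh: str
    omims: list[str]


@dataclass
class _Mutation:
    wt: str
    pos: int
    mut: str
    surface: str

    def one_letter(self) -> str:
        return f"{residues.THREE_TO_ONE[self.wt]}{self.pos}{residues.THREE_TO_ONE[self.mut]}"


# template items: ("w", word) for plain words, ("p"/"d"/"m", entity) for
# single-placeholder entity slots
@dataclass
class _SentencePlan:
    items: list[tuple]
    heads: list[int]
    deprels: list[str]
    extra_deps: dict[int, str] = field(default_factory=dict)  # token -> "head:rel"

    def placeholder(self, item, mut_tokens) -> str:
        kind, ent = item
        if kind == "p":
            return ent.mnemonic
        if kind == "d":
            return ent.mesh
        if kind == "m":
            return mut_tokens[id(ent)]
        raise ValueError(kind)


def _title_plan(pmid: str) -> _SentencePlan:
    return _SentencePlan(
        items=[("w", "Synthetic"), ("w", "abstract"), ("w", pmid), ("w", ".")],
        heads=[2, 0, 2, 2],
        deprels=["amod", "root", "nummod", "punct"],
    )


def _single_plan(p, m, d) -> _SentencePlan:
    return _SentencePlan(
        items=[("w", "A"), ("p", p), ("w", "mutation"), ("w", "("), ("m", m),
               ("w", ")"), ("w", "associated"), ("w", "with"), ("d", d), ("w", ".")],
        heads=[3, 3, 7, 5, 3, 5, 0, 9, 7, 7],
        deprels=["det", "compound", "nsubj", "punct", "appos", "punct", "root",
                 "case", "obl", "punct"],
    )


def _link_a_plan(p, d) -> _SentencePlan:
    return _SentencePlan(
        items=[("w", "Mechanistic"), ("w", "insights"), ("w", "into"), ("d", d),
               ("w", "caused"), ("w", "by"), ("p", p), ("w", "mutations"), ("w", ".")],
        heads=[2, 0, 4, 2, 4, 8, 8, 5, 2],
        deprels=["amod", "root", "case", "nmod", "acl", "case", "compound",
                 "obl", "punct"],
    )


def _link_b_plan(p, m) -> _SentencePlan:
    return _SentencePlan(
        items=[("w", "The"), ("w", "missense"), ("w", "mutation"), ("w", "("),
               ("p", p), ("m", m), ("w", ")"), ("w", "was"), ("w", "functionally"),
               ("w", "characterized"), ("w", ".")],
        heads=[3, 3, 10, 6, 6, 3, 6, 10, 10, 0, 10],
        deprels=["det", "amod", "nsubj", "punct", "compound", "appos", "punct",
                 "aux", "advmod", "root", "punct"],
    )


def _trigger_headline_plan(d) -> _SentencePlan:
    return _SentencePlan(
        items=[("w", "Mutational"), ("w", "spectrum"), ("w", "analysis"),
               ("w", "of"), ("d", d), ("w", ".")],
        heads=[3, 3, 0, 5, 3, 3],
        deprels=["amod", "compound", "root", "case", "nmod", "punct"],
    )


def _trigger_body_plan(p, m) -> _SentencePlan:
    return _SentencePlan(
        items=[("w", "The"), ("p", p), ("m", m), ("w", "variant"), ("w", "was"),
               ("w", "present"), ("w", "in"), ("w", "several"), ("w", "patients"),
               ("w", ".")],
        heads=[4, 3, 4, 6, 6, 0, 9, 9, 6, 6],
        deprels=["det", "compound", "compound", "nsubj", "cop", "root", "case",
                 "amod", "obl", "punct"],
    )


def _absent_plan(ms, d) -> _SentencePlan:
    m1, m2, m3, m4 = ms
    return _SentencePlan(
        items=[("w", "Four"), ("w", "variants"), ("m", m1), ("w", ","), ("m", m2),
               ("w", ","), ("m", m3), ("w", "and"), ("m", m4), ("w", "were"),
               ("w", "identified"), ("w", "in"), ("d", d), ("w", ".")],
        heads=[2, 11, 2, 5, 3, 7, 3, 9, 3, 11, 0, 13, 11, 11],
        deprels=["nummod", "nsubj", "appos", "punct", "conj", "punct", "conj",
                 "cc", "conj", "aux", "root", "case", "obl", "punct"],
        extra_deps={5: "2:appos", 7: "2:appos", 9: "2:appos"},
    )


def _distract_plans(p, m, d) -> list[_SentencePlan]:
    return [
        _SentencePlan(
            items=[("w", "We"), ("w", "studied"), ("p", p), ("w", "expression"),
                   ("w", ".")],
            heads=[2, 0, 4, 2, 2],
            deprels=["nsubj", "root", "compound", "obj", "punct"],
        ),
        _SentencePlan(
            items=[("w", "The"), ("m", m), ("w", "substitution"), ("w", "alters"),
                   ("w", "protein"), ("w", "stability"), ("w", ".")],
            heads=[3, 3, 4, 0, 6, 4, 4],
            deprels=["det", "compound", "nsubj", "root", "compound", "obj", "punct"],
        ),
        _SentencePlan(
            items=[("w", "Severe"), ("d", d), ("w", "was"), ("w", "observed"),
                   ("w", ".")],
            heads=[2, 4, 4, 0, 4],
            deprels=["amod", "nsubj", "aux", "root", "punct"],
        ),
    ]


def _detokenize(surfaces: list[str]) -> tuple[str, list[tuple[int, int]]]:
    """Join surfaces with standard spacing; return text and per-item spans."""
    text = ""
    spans = []
    for i, s in enumerate(surfaces):
        if i > 0 and s not in _NO_SPACE_BEFORE and not text.endswith("("):
            text += " "
        spans.append((len(text), len(text) + len(s)))
        text += s
    return text, spans


def _rand_mutation(rng: random.Random) -> _Mutation:
    wt = rng.choice(_AA)
    mut = rng.choice(_AA)
    pos = rng.randint(30, 900)
    m = _Mutation(wt, pos, mut, "")
    m.surface = m.one_letter() if rng.random() < 0.5 else f"{wt}{pos}{mut}"
    return m


def generate_corpus(spec: CorpusSpec, outdir) -> CorpusPaths:
    """Write a synthetic corpus under *outdir* and return the file paths.

    Deterministic given ``spec.seed``: equal seeds give byte-identical
    files.  The gold TSV labels each tuple with the least capable system
    variant that recovers it (or UNRECOVERABLE).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lexdir = outdir / "lexicons"
    lexdir.mkdir(exist_ok=True)
    rng = random.Random(spec.seed)

    n = spec.n_docs
    n_single = round(n * spec.frac_single_sentence)
    n_link = min(round(n * spec.frac_entity_link), n - n_single)
    n_trig = min(round(n * spec.frac_trigger_link), n - n_single - n_link)
    n_absent = min(round(n * spec.frac_entity_absent), n - n_single - n_link - n_trig)
    classes = (["single"] * n_single + ["entity_link"] * n_link
               + ["trigger_link"] * n_trig + ["entity_absent"] * n_absent)
    classes += ["distractor"] * (n - len(classes))
    rng.shuffle(classes)

    n_pool = n + 2
    proteins = [
        _Protein(name=f"mutadorin {i}", mnemonic=f"MTD{i}_HUMAN",
                 entrez=str(5000 + i), signal=rng.choice(spec.signal_pool))
        for i in range(n_pool)
    ]
    diseases = []
    for i in range(n_pool):
        omims = [str(600000 + i)]
        if i % 5 == 0:
            omims += [str(610000 + i), str(620000 + i)]
        diseases.append(_Disease(name=f"granulopathy {i}",
                                 mesh=f"D{650000 + i}", omims=omims))

    pub_lines: list[str] = []
    conllu_lines: list[str] = []
    gold_rows: list[list] = []

    for j, cls in enumerate(classes):
        pmid = str(9000000 + j)
        prot = proteins[j % n_pool]
        dis = diseases[j % n_pool]

        if cls == "single":
            m = _rand_mutation(rng)
            plans = [_single_plan(prot, m, dis)]
            golds = [(prot, m, dis, "S2_RECOVERABLE")]
        elif cls == "entity_link":
            m = _rand_mutation(rng)
            plans = [_link_a_plan(prot, dis), _link_b_plan(prot, m)]
            golds = [(prot, m, dis, "S4_RECOVERABLE")]
        elif cls == "trigger_link":
            m = _rand_mutation(rng)
            plans = [_trigger_headline_plan(dis), _trigger_body_plan(prot, m)]
            golds = [(prot, m, dis, "S5_RECOVERABLE")]
        elif cls == "entity_absent":
            ms = [_rand_mutation(rng) for _ in range(4)]
            plans = [_absent_plan(ms, dis)]
            golds = [(prot, m, dis, "UNRECOVERABLE") for m in ms]
        else:  # distractor
            m = _rand_mutation(rng)
            plans = _distract_plans(prot, m, dis)
            golds = []

        title_plan = _title_plan(pmid)
        title_surfaces = [it[1] for it in title_plan.items]
        title_text, _ = _detokenize(title_surfaces)

        sentence_texts: list[str] = []
        annotations: list[tuple[int, int, str, str, str]] = []  # sentence-local
        mut_tokens: dict[int, str] = {}
        next_mut = 0
        triple_tokens: dict[tuple, str] = {}

        abstract = ""
        for plan in plans:
            surfaces = []
            for kind, val in plan.items:
                if kind == "w":
                    surfaces.append(val)
                elif kind == "p":
                    surfaces.append(val.name)
                elif kind == "d":
                    surfaces.append(val.name)
                else:
                    surfaces.append(val.surface)
                    key = (val.wt, val.pos, val.mut)
                    if key not in triple_tokens:
                        triple_tokens[key] = f"MUT{next_mut}"
                        next_mut += 1
                    mut_tokens[id(val)] = triple_tokens[key]
            text, spans = _detokenize(surfaces)
            base = len(abstract) + (1 if abstract else 0)
            abstract = f"{abstract} {text}" if abstract else text
            for (kind, val), (s, e) in zip(plan.items, spans):
                if kind == "w":
                    continue
                if kind == "p":
                    annotations.append((base + s, base + e, val.name, "Gene", val.entrez))
                elif kind == "d":
                    annotations.append((base + s, base + e, val.name, "Disease",
                                        f"MESH:{val.mesh}"))
                else:
                    annotations.append((base + s, base + e, val.surface, "Mutation",
                                        f"p.{val.one_letter()}"))
            sentence_texts.append(text)

        pub_lines.append(f"{pmid}|t|{title_text}")
        pub_lines.append(f"{pmid}|a|{abstract}")
        doc_offset = len(title_text) + 1
        for s, e, surface, ann_type, norm in annotations:
            pub_lines.append("\t".join([pmid, str(doc_offset + s), str(doc_offset + e),
                                        surface, ann_type, norm]))
        pub_lines.append("")

        for sent_index, plan in [(0, title_plan)] + list(enumerate(plans, start=1)):
            conllu_lines.append(f"# pmid = {pmid}")
            conllu_lines.append(f"# sent_id = {sent_index}")
            for t, (item, head, rel) in enumerate(
                    zip(plan.items, plan.heads, plan.deprels), start=1):
                form = item[1] if item[0] == "w" else plan.placeholder(item, mut_tokens)
                deps = plan.extra_deps.get(t, "_")
                conllu_lines.append("\t".join([
                    str(t), form, form.lower(), "_", "_", "_",
                    str(head), rel, deps, "_"]))
            conllu_lines.append("")

        for prot_g, m_g, dis_g, label in golds:
            gold_rows.append([pmid, prot_g.mnemonic, m_g.wt,
                              m_g.pos + prot_g.signal, m_g.pos, m_g.mut,
                              dis_g.omims[0], label])

    pub_path = outdir / "corpus.pubtator"
    pub_path.write_text("\n".join(pub_lines) + "\n", encoding="utf-8")
    conllu_path = outdir / "corpus.conllu"
    conllu_path.write_text("\n".join(conllu_lines) + "\n", encoding="utf-8")

    (lexdir / "proteins.tsv").write_text(
        "name\tuniprot\tentrez\n" + "".join(
            f"{p.name}\t{p.mnemonic}\t{p.entrez}\n" for p in proteins),
        encoding="utf-8")
    (lexdir / "diseases.tsv").write_text(
        "name\tmesh\n" + "".join(f"{d.name}\t{d.mesh}\n" for d in diseases),
        encoding="utf-8")
    (lexdir / "mesh_omim.tsv").write_text(
        "mesh\tomim\n" + "".join(
            f"{d.mesh}\t{o}\n" for d in diseases for o in d.omims),
        encoding="utf-8")
    (lexdir / "signal_peptides.tsv").write_text(
        "uniprot\tlength\n" + "".join(
            f"{p.mnemonic}\t{p.signal}\n" for p in proteins),
        encoding="utf-8")
    (lexdir / "triggers.tsv").write_text(
        "word\tclass\n" + "".join(
            f"{w}\t{c}\n" for w, c in sorted(DEFAULT_TRIGGERS.items())),
        encoding="utf-8")

    gold_path = outdir / "gold.tsv"
    header = "pmid\tuniprot_id\twt\tpos_db\tpos_text\tmut\tomim_id\tlabel\n"
    gold_path.write_text(
        header + "".join("\t".join(str(x) for x in row) + "\n" for row in gold_rows),
        encoding="utf-8")

    return CorpusPaths(pub_path, conllu_path, lexdir, gold_path)
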