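# Methods

This note documents the models and procedures implemented in `mutrel`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic corpora do and do not establish.

## Problem setting

The package extracts ternary protein–point-mutation–disease
associations from abstracts and evaluates them against gold tuples
derived from curated variant records rather than from text-span
annotations. Scope is deliberately restricted to single amino-acid
substitutions (`wNm`); insertions, deletions and nucleotide-level
variants are out of scope.

## Entity layer

**Substitution grammar.** Mentions are matched by a small editable
pattern table (`resources/mutation_patterns.tsv`): 1-letter `wNm`
(`R203C`, optional `p.`), 3-letter compact (`Ser169Pro`, `SER-409-PRO`),
and spelled forms with a connector ("aspartate 399 to asparagine",
arrows). Matches are normalized to a (wt, pos, mut) triple in 3-letter
codes; overlaps resolve to the longest span. Identifier look-alikes
("A2B") are suppressed by requiring non-alphanumeric boundaries, and
wt = mut is allowed — silent substitutions do occur in text. Codon-level
spellings ("codon 444, Leu (CTG) to Pro (CCG)") are a documented known
miss of this grammar family; an extended pattern exists behind the
`extended` flag but is off by default so that the default behaviour
reflects what such grammars actually catch.

**Dictionary tagging.** Protein and disease names are matched by
longest-first lookup over token boundaries after lexical normalization
(case folding, punctuation to spaces, whitespace collapsed). Lexicons
are plain TSVs: name → UniProt mnemonic + Entrez id, name → MeSH id,
MeSH → OMIM (one row per pair; several rows per MeSH id are legal and
all retained), mnemonic → signal-peptide length.

**Abbreviations.** Parenthesized short forms (2–10 characters, at least
one letter) are resolved against a window of at most
min(|SF|+5, |SF|·2) words inside the same sentence by right-to-left
greedy character matching; the first short-form character must start a
word. When the long form overlaps a tagged protein or disease, all
other occurrences of the short form in the abstract inherit its class
and ids.

**Merging.** Annotations from several sources (supplied PubTator-style
annotations plus the package's own taggers) are consolidated: same-class
overlaps collapse to the longest span with the union of ids;
identical-span cross-class conflicts resolve by MUTATION > PROTEIN >
DISEASE; other cross-class overlaps keep both readings. The operation is
idempotent.

## Simplification

Each mention is replaced by a single parser-safe token: the UniProt
mnemonic (hyphens/periods → underscore), the MeSH id, or `MUT` plus an
index. Mutation indices are scoped to the *document*, assigned in order
of first occurrence, and identical triples share an index — this is
what lets two sentences mention "the same" mutation and be linked; a
sentence-scoped index could not support identity linking. Unnormalized
proteins receive `PROTk` placeholders so parsing still works, but
tuples built on them are dropped at assembly (they can never match a
database-keyed gold). The substitution record retains exact spans, so
de-substitution reproduces the original sentence byte-for-byte (a
property the suite asserts on every fixture).

## Graph traversal

Parses are consumed from CoNLL-U; HEAD/DEPREL rows become undirected
labeled edges and the enhanced-dependencies column supplies
collapsed-preposition and propagated-conjunction edges. The parser
itself is a pluggable input: any tool that emits CoNLL-U over the
simplified sentences works, and all tests use fixture parses.

*Common node.* Three entities in one sentence are related iff some node
lies on all three pairwise shortest paths, endpoints included. Including
endpoints is essential: in appositions like "PSN1_HUMAN mutation
(MUT0)", the hub is the protein token itself. Ties resolve to the
smallest token id. Equivalence with a brute-force path-enumeration
oracle is asserted on a thousand random trees of up to 15 nodes.

*Binary relations.* Plain connectivity would make graph-based binary
extraction identical to sentence co-occurrence, so a pair is related
only if no other entity of either endpoint's class lies on a shortest
path between them (the *interposition filter*). This is a heuristic: it
correctly excludes "P1 ... P2-M" chains while the propagated
conjunction edges keep legitimate conjoined entities reachable.

## Discourse linking

*Identity (S4).* Graphs sharing a placeholder token merge transitively;
two binary relations from different sentences of one component that
share an entity and jointly cover {P, M, D} compose into a ternary
relation. Same-sentence composition is excluded — within a sentence the
common-node rule is the arbiter.

*Triggers/anaphora (S5).* Trigger nouns are matched on lemma against a
configurable lexicon (default: mutation/mutant/mutational/variant/
variation → MUTATION; patient/phenotype → DISEASE, with plural forms).
A trigger resolves to the nearest entity of its class in the nearest
preceding sentence, falling back to the nearest following sentence; the
resolution window is the whole abstract (abstracts are short), and
resolution is one-to-one per trigger node. The trigger node is then
aliased to the entity token and extraction re-runs on the augmented
graph. Pronouns are handled by the same nearest-compatible-antecedent
rule; no full coreference resolver is included. Trigger linking is
deliberately recall-oriented: the test suite pins down its
characteristic failure, a headline "Mutational ..." capturing a
mutation from an unrelated sentence and composing a spurious tuple.

Linking only ever adds relations, which gives the central invariant
S3 ⊆ S4 ⊆ S5 (⊆ S1) on per-document tuple sets, asserted corpus-wide.

## Post-processing and scoring

Ternary relations become normalized tuples: `pos_db = pos_text +
signal_length` (0 when the protein has no signal annotation or is
unknown), residues in 3-letter codes, MeSH → OMIM with *all* mapped ids
retained. Deduplication keys on the database-space position so the same
biological variant reported with and without the offset collapses. The
co-occurrence baselines pass through the identical post-processing, so
all five variants are compared on one tuple space.

Matching against gold requires the same PMID, UniProt id and residues,
a position agreeing in *either* coordinate space (robust to unknown
signal lengths — it mirrors the curator's adjustment), and non-empty
OMIM intersection; binary types use the corresponding field subsets.
Gold built from SwissProt-style flat records (via Biopython) keeps both
coordinate spaces per record: `pos_text_expected = pos_db − signal`.
Variants curated without a disease link enter the protein–mutation gold
only. Precision, recall and F are reported in percent with zero-guards;
TP counts matched system tuples, FN unmatched gold, after
per-relation-type deduplication on both sides.

Recall errors are categorized automatically: a false negative whose
gold protein (by normalized id), variant (triple, either coordinate
space) or disease (by mapped OMIM id) never appears in the abstract is
an ENTITY_ABSENT error of that class (checked in the order protein,
mutation, disease); otherwise it is an EXTRACTION_MISS. Judging whether
a false *positive* is a true association missing from the database is a
manual act and out of scope.

The corpus filter retains abstracts with at least one mention of each
class; the development/test split is a seeded random shuffle with
`round(n·fraction)` development items — 720 abstracts at 0.8 split into
576/144.

## Synthetic corpora

The generator emulates the discourse regimes that drive the variant
ladder, using fixed sentence templates whose dependency trees (with
propagated-conjunction enhanced edges) are emitted alongside the text,
so no live parser is needed anywhere. Default mixture per document:
36 % single-sentence triples (apposition shape), 25 % split across
sentences sharing the protein ("caused by" + characterization shape),
15 % linkable only through a trigger headline, 15 % abstracts where the
gold protein is never mentioned (four variants each — the dominant
recall-error regime), remainder distractors with all three classes but
no gold association. The single-sentence share follows the observed
within-sentence rate of about a third; the entity-absent share keeps
absence the leading recall-error cause without letting it dominate the
corpus. Signal-peptide lengths are drawn from {0, 0, 0, 19, 24, 39,
72}, so most synthetic proteins have no offset and the nonzero ones
exercise the adjustment. Generation is deterministic: equal seeds give
byte-identical files, and each gold tuple is labeled with the least
capable variant that recovers it (label soundness is itself a test).

What passing on synthetic corpora shows: the mechanics — grammar,
placeholder bookkeeping, traversal, linking, coordinate arithmetic,
scoring — are correct under controlled discourse structure. What it
does not show: robustness to parser errors, nested/discontinuous
mentions, lexicon gaps, or naturalistic paraphrase; template sentences
are grammatically regular and the lexicons are complete by
construction. Corpus-level metrics on real literature depend on those
factors and on the external resources used.

## Numerical and procedural choices

* Traversal is undirected over the collapsed graph; shortest-path
  computations are breadth-first (unit edge weights).
* Common-node ties → smallest token id; trigger-candidate ties →
  nearest sentence, then smallest token id.
* Degenerate inputs: empty sentences, mention-free sentences and
  missing parses are legal (the sentence then contributes only to the
  co-occurrence baselines, logged); a parse block whose HEAD exceeds
  the token count is skipped; an annotation whose span text mismatches
  the document is dropped with a warning.
* The title is processed as sentence 0; the rule-based splitter never
  splits inside parentheses, protecting "(Ser169Pro)".
* PubTator offsets are 0-based half-open over title + single space +
  abstract.
* Evaluation sizes in the test suite: property checks on a
  200-document synthetic corpus and 1,000 random trees — large enough
  to exercise every discourse class several dozen times while keeping
  the whole suite in a few seconds.

## Known limitations

* Binary extraction's interposition filter is a heuristic without a
  linguistic guarantee; it can suppress legitimate pairs in dense
  entity clusters not bridged by conjunction edges.
* One-to-one trigger resolution cannot represent a trigger standing for
  several antecedents.
* Entity normalization is dictionary-based; no machine-learned NER or
  species disambiguation is included, so lexicon coverage bounds
  recall on real text.
* dbSNP identifiers are parsed but unused downstream, as the gold is
  residue-based.
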