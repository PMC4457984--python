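"""Small shared utilities for the test suite."""

from mutrel import Corpus, extract_corpus
from mutrel.gold_eval import GoldRecord, _matches


def ternary_keys(tuples):
    """Canonical identity of ternary tuples, in database space."""
    return {
        (t.pmid, t.uniprot_id, t.wt, t.pos_norm, t.mut, t.omim_ids)
        for t in tuples
        if t.uniprot_id and t.wt and t.omim_ids
    }


def run_all_systems(corpus: Corpus):
    return {s: extract_corpus(corpus, s) for s in ("S1", "S2", "S3", "S4", "S5")}


def gold_recovered(gold: GoldRecord, tuples) -> bool:
    return any(_matches(t, gold, "PMD") for t in tuples
               if t.uniprot_id and t.wt and t.omim_ids)
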