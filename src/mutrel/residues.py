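"""Amino-acid code tables: 1-letter <-> 3-letter <-> full residue names.

Substitution mentions in text use any of the three spellings; the
normalized in-memory form is always the capitalized 3-letter code
(``Ser``, ``Arg``, ...), matching how curated variant databases print
residues.
"""

from __future__ import annotations

#: canonical 3-letter codes of the 20 proteinogenic residues
ONE_TO_THREE: dict[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

THREE_TO_ONE: dict[str, str] = {v: k for k, v in ONE_TO_THREE.items()}

THREE_LETTER_CODES: frozenset[str] = frozenset(THREE_TO_ONE)

#: full residue names (lowercase) -> 3-letter code; common variants included
FULL_TO_THREE: dict[str, str] = {
    "alanine": "Ala",
    "arginine": "Arg",
    "asparagine": "Asn",
    "aspartate": "Asp",
    "aspartic acid": "Asp",
    "cysteine": "Cys",
    "glutamine": "Gln",
    "glutamate": "Glu",
    "glutamic acid": "Glu",
    "glycine": "Gly",
    "histidine": "His",
    "isoleucine": "Ile",
    "leucine": "Leu",
    "lysine": "Lys",
    "methionine": "Met",
    "phenylalanine": "Phe",
    "proline": "Pro",
    "serine": "Ser",
    "threonine": "Thr",
    "tryptophan": "Trp",
    "tyrosine": "Tyr",
    "valine": "Val",
}


def to_three(code: str) -> str | None:
    """Normalize any residue spelling to the 3-letter code, or None."""
    code = code.strip()
    if len(code) == 1 and code.upper() in ONE_TO_THREE:
        return ONE_TO_THREE[code.upper()]
    if len(code) == 3 and code.capitalize() in THREE_TO_ONE:
        return code.capitalize()
    return FULL_TO_THREE.get(code.lower())
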