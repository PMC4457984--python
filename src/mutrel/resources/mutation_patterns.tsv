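# Point-substitution mention grammar.
# Columns: name <TAB> flags (I = case-insensitive, X = extended/off by default) <TAB> regex
# {AA1} / {AA3} / {AAW} expand to the 1-letter, 3-letter and 3-letter-or-full-name
# residue alternations at load time.  Every pattern must define named groups
# wt, pos, mut.
one_letter	-	(?<![A-Za-z0-9])(?:p\.)?(?P<wt>{AA1})(?P<pos>[1-9]\d*)(?P<mut>{AA1})(?![A-Za-z0-9])
three_letter	I	(?<![A-Za-z])(?:p\.)?(?P<wt>{AA3})-?(?P<pos>[1-9]\d*)-?(?P<mut>{AA3})(?![A-Za-z0-9])
spelled_connector	I	(?<![A-Za-z])(?P<wt>{AAW})[\s-]*(?:residue[\s-]+)?(?:at[\s-]+position[\s-]+)?(?P<pos>[1-9]\d*)\s*(?:-->|->|→|to|is[\s-]+replaced[\s-]+by|was[\s-]+replaced[\s-]+by|replaced[\s-]+by|substituted[\s-]+(?:by|with))\s*(?P<mut>{AAW})(?![A-Za-z])
codon_level	IX	codon\s+(?P<pos>[1-9]\d*)\s*[,:]?\s*(?P<wt>{AAW})\s*\([ACGTU]{3}\)\s*to\s*(?P<mut>{AAW})\s*\([ACGTU]{3}\)
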