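"""Unit conventions: internals are atomic units, reports are kcal/mol and Å."""

HARTREE_TO_KCAL = 627.509
BOHR_PER_ANGSTROM = 1.0 / 0.52917721092
ANGSTROM_PER_BOHR = 0.52917721092
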