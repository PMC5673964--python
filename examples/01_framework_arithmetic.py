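"""Parse published cysteine-framework motifs and check their arithmetic.

Motif strings as printed in the literature mix Cyrillic and Latin C's and
decorate spacers with hyphens; the parser normalises them, and `span` /
`cys_count` verify the stated mature lengths and cysteine counts.
"""

import venomminer as vm

MOTIFS = {
    "symmetric 8-Cys toxin": "С1С-3-С3С-4-С3С-3-С1С3",
    "crotamine-like toxin": "C8C-3-C11C-5-CC6",
    "vicinal-triplet toxin": "C27C4C4-CCC",
    "general group-1 pattern": "C1C##C[6–9]C-[6–9]-CC#",
}

for name, motif in MOTIFS.items():
    fw = vm.parse_motif(motif)
    lo, hi = vm.span(fw)
    print(f"{name}:")
    print(f"  printed   {motif}")
    print(f"  canonical {vm.format_motif(fw)}")
    print(f"  cysteines {vm.cys_count(fw)}, span {lo}"
          + (f"-{hi}" if hi not in (None, lo) else ("+" if hi is None else "")))

# span is the realised mature length for fully exact motifs: the symmetric
# 8-Cys motif spans exactly 29 residues, the crotamine-like one exactly 39;
# the general pattern is open-ended (22+), as befits a family-level motif.
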