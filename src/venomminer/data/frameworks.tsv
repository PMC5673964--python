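# Default structural-group registry for sea anemone venom peptides.
# One entry per line: label<TAB>motif.  '#' comments only at line start
# (inside a motif, '#' is an open spacer term).
# The named groups follow the field's cysteine-distribution nomenclature;
# spacer values are editable — extend this file with further groups as needed.
1a	C1C5C10C6CC
1b	C1C7C9C8CC
1c	C1C3C12C7CC
3a	C8C15C7C12C3C
6a	C4C6C4C8CC
8a	C6C4C9C3CC
10a	C9C3C5C7C3C
11b	C6C6CC6CC
linear	-
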