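"""Classify mature peptides against the structural-group registry.

Builds three peptides — one realising a registry framework, one with a
novel cysteine arrangement, one cysteine-free — and classifies each.
"""

import numpy as np

import venomminer as vm

registry = vm.load_registry()
rng = np.random.default_rng(0)

known = vm.gen_mature(registry["8a"], vm.span(registry["8a"])[0] + 10, rng)
novel = "CCW" + "ADE" * 5 + "CC" + "GHIK" * 3  # vicinal pairs, unregistered
linear = vm.gen_mature(vm.LINEAR, 35, rng)

for name, seq in (("known-group", known), ("novel", novel),
                  ("cys-free", linear)):
    label = vm.classify(seq, registry)
    motif = vm.format_motif(vm.extract_framework(seq))
    print(f"{name:12s} {label:7s} {motif:24s} {seq}")

# "8a" means the peptide realises that group's spacer pattern; "new" flags
# a framework matching no registry entry (novelty detection, not an error);
# "linear" marks cysteine-free polypeptides.
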