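"""Validate predicted precursors against tryptic-peptide evidence.

Digests planted precursors in silico, emits 3 evidence peptides for most
proteins but at most 1 for two designated proteins, and shows that exactly
the two-peptide proteins validate, with their sequence coverage.
"""

import venomminer as vm

sc = vm.make_scenario(seed=4, n_planted=6, n_decoys=0, n_unvalidatable=2)
preds = [p.precursor for p in sc.truth.planted]
reports = vm.match_evidence(sc.evidence, preds, tol_ppm=10, max_missed=1)

print(f"{'protein':14s} {'peptides':>8s} {'coverage':>9s}  validated")
for rep in reports:
    print(f"{rep.protein_id:14s} {rep.n_distinct_peptides:8d} "
          f"{100 * rep.coverage:8.1f}%  {rep.validated}")

# A precursor validates only when >= 2 distinct tryptic peptides match it
# (by exact sequence, or by monoisotopic mass within the ppm tolerance);
# coverage is the fraction of the precursor under the matched spans.
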