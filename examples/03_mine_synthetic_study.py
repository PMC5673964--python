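"""Mine a small synthetic transcriptome with the group-binning strategy.

Generates 6 planted toxin mRNAs among 40 decoys, tiles error-free reads at
20x, bins reads by homology to per-group reference sets, assembles each
bin, filters precursors, classifies frameworks, and scores recovery
against the ground truth.
"""

import venomminer as vm
from venomminer.evaluate import evaluate_recovery
from venomminer.pipeline import RunConfig, run_method3

sc = vm.make_scenario(seed=3, n_planted=6, n_decoys=40)
print(f"inputs: {len(sc.transcripts)} transcripts, {len(sc.reads)} reads, "
      f"{len(sc.group_sets)} group reference sets")

cfg = RunConfig(e_max=sc.e_max, seed=sc.seed)
cands = vm.run_method3(sc.reads, sc.group_sets, cfg, sc.registry)
survivors = [c for c in cands if c.passed]
print(f"scanned {len(cands)} ORFs, {len(survivors)} passed the "
      f"four-rule precursor filter")

for c in survivors:
    print(f"  {c.group_bin:4s} {c.framework_label:7s} "
          f"mature={c.mature.seq[:30]}... ({len(c.mature.seq)} aa)")

rep = evaluate_recovery(cands, sc.truth, sc.reads)
print(f"recovered and correctly classified {rep.n_recovered}/{rep.n_planted} "
      f"planted toxins; base-perfect matures: {sum(rep.exact_mature.values())}")
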