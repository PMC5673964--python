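"""Scoring pipeline output against a synthetic ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .curate import PrecursorCandidate
from .seqio import NucRecord
from .simulate import GroundTruth, read_origin


@dataclass
class RecoveryReport:
    n_planted: int
    n_recovered: int
    recovered_ids: List[str] = field(default_factory=list)
    exact_mature: Dict[str, bool] = field(default_factory=dict)

    @property
    def fraction(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else 1.0


def evaluate_recovery(candidates: Sequence[PrecursorCandidate],
                      truth: GroundTruth,
                      reads: Optional[Sequence[NucRecord]] = None,
                      min_member_frac: float = 0.5) -> RecoveryReport:
    """Which planted toxins were recovered and correctly classified?

    A planted toxin counts as recovered when some surviving candidate (a)
    derives from a contig whose member reads are mostly from the toxin's
    transcript (when read provenance is available; otherwise the candidate's
    mature must equal the planted mature), and (b) is classified to the
    toxin's declared structural group.  ``exact_mature`` additionally records
    whether the recovered mature sequence is base-perfect.
    """
    origin = {}
    if reads is not None:
        origin = {r.id: read_origin(r) for r in reads}
    report = RecoveryReport(n_planted=len(truth.planted), n_recovered=0)
    survivors = [c for c in candidates if c.passed]
    for planted in truth.planted:
        hit = None
        for cand in survivors:
            if cand.framework_label != planted.framework_label:
                continue
            if origin and cand.source_members:
                origins = [origin.get(rid) for rid in cand.source_members]
                frac = sum(o == planted.transcript_id for o in origins) / len(origins)
                if frac >= min_member_frac:
                    hit = cand
                    if cand.mature and cand.mature.seq == planted.mature_seq:
                        break  # prefer an exact recovery when one exists
            elif cand.mature and cand.mature.seq == planted.mature_seq:
                hit = cand
                break
        if hit is not None:
            report.n_recovered += 1
            report.recovered_ids.append(planted.protein_id)
            report.exact_mature[planted.protein_id] = bool(
                hit.mature and hit.mature.seq == planted.mature_seq
            )
    return report
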