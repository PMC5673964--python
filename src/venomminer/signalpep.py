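"""Heuristic signal-peptide detection and cleavage-site prediction.

Secreted toxin precursors begin with an N-terminal signal peptide whose
classical architecture has three parts: a short positively charged n-region,
a hydrophobic h-region core, and a c-region whose cleavage site follows the
(-3,-1) small-residue rule.  This module codifies that architecture as a
transparent, deterministic rule set (a von Heijne-style heuristic) so the
pipeline is self-contained and testable end to end:

* n-rule — at least one K/R within the first 5 residues;
* h-rule — some 8-residue window inside positions 3-20 has mean
  Kyte-Doolittle hydropathy >= 1.6;
* c-rule — a position ``p`` in [12, 40], at least 2 past the h-window end,
  with the residues at ``p-2`` and ``p`` both small (A/G/S/T/C); cleavage is
  after the smallest such ``p`` and the mature peptide starts at ``p+1``.

All thresholds are explicit parameters of :class:`SignalParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

# Kyte & Doolittle hydropathy index — the single hydropathy scale used.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


@dataclass(frozen=True)
class SignalParams:
    window: int = 8                 # h-region window width (residues)
    min_hydropathy: float = 1.6     # mean KD hydropathy required in the window
    small_set: str = "AGSTC"        # residues allowed at the -3/-1 positions
    n_region_len: int = 5           # prefix scanned for a K/R
    h_first: int = 3                # 1-based first position of the h-scan
    h_last: int = 20                # 1-based last position of the h-scan
    cleavage_min: int = 12          # 1-based bounds on the cleavage position
    cleavage_max: int = 40
    min_len: int = 20               # shorter precursors cannot carry a signal


@dataclass
class SignalCall:
    """Outcome of signal-peptide detection on a precursor.

    ``cleavage_pos`` is the 1-based index of the last signal residue; the
    mature peptide starts at ``cleavage_pos + 1``.  ``score`` is the best
    h-window mean hydropathy (higher = more signal-like).
    """

    present: bool
    cleavage_pos: Optional[int] = None
    score: Optional[float] = None
    reason: Optional[str] = None


def score_signal(prec, params: SignalParams = SignalParams()) -> SignalCall:
    """Apply the n/h/c rules to a precursor and predict the cleavage site."""
    seq = prec.seq if hasattr(prec, "seq") else str(prec)
    if len(seq) < params.min_len:
        return SignalCall(present=False, reason="too short")

    # n-rule: positive charge near the N-terminus
    if not any(c in "KR" for c in seq[: params.n_region_len]):
        return SignalCall(present=False, reason="no K/R in n-region")

    # h-rule: hydrophobic core window within positions h_first..h_last
    best = None
    best_end = None  # 1-based index of the last residue of the best window
    first0 = params.h_first - 1
    last_start0 = params.h_last - params.window
    for i0 in range(first0, last_start0 + 1):
        win = seq[i0 : i0 + params.window]
        mean = sum(KYTE_DOOLITTLE.get(c, 0.0) for c in win) / params.window
        if best is None or mean > best:
            best = mean
            best_end = i0 + params.window
    if best is None or best < params.min_hydropathy:
        return SignalCall(present=False, score=best, reason="no hydrophobic core")

    # c-rule: (-3,-1) small residues, cleavage after the smallest eligible p
    p_lo = max(params.cleavage_min, best_end + 2)
    p_hi = min(params.cleavage_max, len(seq))
    for p in range(p_lo, p_hi + 1):
        if seq[p - 3] in params.small_set and seq[p - 1] in params.small_set:
            return SignalCall(present=True, cleavage_pos=p, score=best)
    return SignalCall(present=False, score=best, reason="no cleavage site")
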