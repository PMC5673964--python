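"""Translated local-alignment homology search.

Candidate toxin transcripts are found by aligning six-frame translations of
reads (or contigs) against protein reference sets of known toxins, one set
per structural group.  Alignment is exact Smith-Waterman (BLOSUM62, affine
gaps: opening a gap of length k costs 11 + k) via Biopython's C-implemented
``PairwiseAligner`` — the reference sets are small enough that exactness is
affordable.  Significance uses Karlin-Altschul statistics with the gapped
BLOSUM62-11/1 constants, E = K·m·n·exp(−λ·score).

Stop codons split a frame translation into segments that are aligned
independently, approximating how a translating search tool treats
interrupted frames; frameshift-aware alignment is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from .orfs import six_frame_translate
from .seqio import NucRecord, ProtRecord

#: Karlin-Altschul constants for gapped BLOSUM62 with 11/1 gap costs.
KA_K = 0.041
KA_LAMBDA = 0.267

GAP_OPEN = 11   # gap existence cost
GAP_EXTEND = 1  # per-residue cost (a k-long gap costs GAP_OPEN + k*GAP_EXTEND)


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # Biopython charges open_gap_score for the first gap residue and
    # extend_gap_score for each further one; BLAST-style 11/1 is therefore
    # open = -(11 + 1), extend = -1.
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


@dataclass
class AlignmentHit:
    """A local alignment between a (translated) query and a reference."""

    query_id: str
    ref_id: str
    score: int
    evalue: float
    identity: float
    q_span: Tuple[int, int]  # 0-based half-open; nt coords for translated hits
    r_span: Tuple[int, int]
    frame: int = 0           # query reading frame; 0 = protein-level query
    aligned_len: int = 0
    mismatches: int = 0
    gaps: int = 0


@dataclass
class ReferenceSet:
    """A labelled protein reference set (one structural group, or a pooled DB)."""

    label: str
    records: List[ProtRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"reference set {self.label!r} is empty")

    @property
    def total_length(self) -> int:
        return sum(len(r.seq) for r in self.records)

    def concat_db(self, sep: str = "X" * 10) -> str:
        return sep.join(r.seq for r in self.records)

    def kmer_index(self, k: int = 4) -> frozenset:
        kmers = set()
        for r in self.records:
            s = r.seq
            for i in range(len(s) - k + 1):
                kmers.add(s[i : i + k])
        return frozenset(kmers)


def evalue(score: float, m: int, n: int,
           K: float = KA_K, lam: float = KA_LAMBDA) -> float:
    """Karlin-Altschul expected number of chance hits of >= this score."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return K * m * n * math.exp(-lam * score)


def _alignment_stats(alignment) -> Tuple[int, int, int, int]:
    """(aligned columns, identities, mismatches, gap columns)."""
    qa, ra = str(alignment[0]), str(alignment[1])
    ident = mism = gaps = 0
    for a, b in zip(qa, ra):
        if a == "-" or b == "-":
            gaps += 1
        elif a == b:
            ident += 1
        else:
            mism += 1
    return len(qa), ident, mism, gaps


def sw_align(q: ProtRecord, r: ProtRecord) -> Optional[AlignmentHit]:
    """Best Smith-Waterman local alignment of two proteins, or None.

    Returns None when no positive-scoring local alignment exists.  Sequences
    must be stop-free: translate and split on stops first.
    """
    for rec in (q, r):
        if "*" in rec.seq:
            raise ValueError(f"stop symbol in {rec.id!r}; trim at stops first")
    aligner = _aligner()
    score = aligner.score(q.seq, r.seq)
    if score <= 0:
        return None
    alignment = aligner.align(q.seq, r.seq)[0]
    cols, ident, mism, gaps = _alignment_stats(alignment)
    q_span = (int(alignment.coordinates[0][0]), int(alignment.coordinates[0][-1]))
    r_span = (int(alignment.coordinates[1][0]), int(alignment.coordinates[1][-1]))
    return AlignmentHit(
        query_id=q.id,
        ref_id=r.id,
        score=int(score),
        evalue=evalue(score, len(q.seq), len(r.seq)),
        identity=ident / cols if cols else 0.0,
        q_span=q_span,
        r_span=r_span,
        frame=0,
        aligned_len=cols,
        mismatches=mism,
        gaps=gaps,
    )


def _frame_segments(read: NucRecord, min_segment_aa: int):
    """Stop-free aa segments per frame: yields (frame, aa_offset, segment)."""
    for frame, prot in six_frame_translate(read).items():
        off = 0
        for seg in prot.seq.split("*"):
            if len(seg) >= min_segment_aa:
                yield frame, off, seg
            off += len(seg) + 1


def _aa_to_nt_span(frame: int, nt_len: int, aa_lo: int, aa_hi: int) -> Tuple[int, int]:
    """Map an aa interval on a frame translation to forward-strand nt coords."""
    off = abs(frame) - 1
    s, e = off + 3 * aa_lo, off + 3 * aa_hi
    if frame > 0:
        return (s, e)
    return (nt_len - e, nt_len - s)


def translated_search(read: NucRecord, refs: ReferenceSet,
                      e_max: float = 1.0,
                      min_segment_aa: int = 8) -> List[AlignmentHit]:
    """Six-frame search of a read against a reference set.

    Keeps the best hit per (frame, reference) pair with E <= ``e_max``
    (E computed against the whole set's residue count, the database
    convention), sorted by (E-value, reference id, frame).
    """
    if len(read.seq) < 3:
        raise ValueError("read shorter than one codon")
    aligner = _aligner()
    n_db = refs.total_length
    best: Dict[Tuple[int, str], Tuple[float, int, int, str]] = {}
    for frame, aa_off, seg in _frame_segments(read, min_segment_aa):
        for ref in refs.records:
            score = aligner.score(seg, ref.seq)
            if score <= 0:
                continue
            key = (frame, ref.id)
            if key not in best or score > best[key][0]:
                best[key] = (score, aa_off, len(seg), seg)
    hits: List[AlignmentHit] = []
    for (frame, ref_id), (score, aa_off, seg_len, seg) in best.items():
        E = evalue(score, seg_len, n_db)
        if E > e_max:
            continue
        ref = next(r for r in refs.records if r.id == ref_id)
        alignment = aligner.align(seg, ref.seq)[0]
        cols, ident, mism, gaps = _alignment_stats(alignment)
        qa_lo = int(alignment.coordinates[0][0])
        qa_hi = int(alignment.coordinates[0][-1])
        hits.append(
            AlignmentHit(
                query_id=read.id,
                ref_id=ref_id,
                score=int(score),
                evalue=E,
                identity=ident / cols if cols else 0.0,
                q_span=_aa_to_nt_span(frame, len(read.seq),
                                      aa_off + qa_lo, aa_off + qa_hi),
                r_span=(int(alignment.coordinates[1][0]),
                        int(alignment.coordinates[1][-1])),
                frame=frame,
                aligned_len=cols,
                mismatches=mism,
                gaps=gaps,
            )
        )
    hits.sort(key=lambda h: (h.evalue, h.ref_id, h.frame))
    return hits


def _read_kmers(read: NucRecord, min_segment_aa: int, k: int) -> set:
    kmers = set()
    for _, _, seg in _frame_segments(read, min_segment_aa):
        for i in range(len(seg) - k + 1):
            kmers.add(seg[i : i + k])
    return kmers


def bin_reads(reads: Sequence[NucRecord], group_sets: Sequence[ReferenceSet],
              e_max: float = 1.0, min_segment_aa: int = 8,
              prescreen_k: Optional[int] = 4) -> Dict[str, List[str]]:
    """Assign reads to every structural group they share similarity with.

    A read enters a group's bin when some six-frame segment aligns to the
    group's reference database at E <= ``e_max``; multi-membership is allowed
    and unassigned reads are dropped.  ``prescreen_k`` enables a BLAST-like
    exact k-mer prescreen (a read segment sharing no k-mer with a set skips
    the alignment); set it to ``None`` for pure exhaustive scoring.  The
    prescreen can only skip pairs whose alignments are far below any
    practical threshold.  Scoring is against the set's concatenated database.
    """
    if not group_sets:
        raise ValueError("at least one group reference set is required")
    aligner = _aligner()
    sets = []
    for gs in group_sets:
        sets.append(
            (
                gs.label,
                gs.concat_db(),
                gs.total_length,
                gs.kmer_index(prescreen_k) if prescreen_k else None,
            )
        )
    bins: Dict[str, List[str]] = {}
    for read in reads:
        if len(read.seq) < 3:
            continue
        segments = [(len(seg), seg) for _, _, seg in
                    _frame_segments(read, min_segment_aa)]
        if not segments:
            continue
        rk = _read_kmers(read, min_segment_aa, prescreen_k) if prescreen_k else None
        for label, db, n_db, kindex in sets:
            if kindex is not None and rk is not None and rk.isdisjoint(kindex):
                continue
            for seg_len, seg in segments:
                score = aligner.score(seg, db)
                if score > 0 and evalue(score, seg_len, n_db) <= e_max:
                    bins.setdefault(label, []).append(read.id)
                    break
    return bins


def write_hits_tsv(hits: Iterable[AlignmentHit], path) -> None:
    """12-column tabular hit report in the conventional blast layout."""
    with Path(path).open("w") as fh:
        fh.write(
            "#query\tref\tidentity\tlength\tmismatches\tgaps"
            "\tqstart\tqend\trstart\trend\tevalue\tscore\n"
        )
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.ref_id}\t{100 * h.identity:.1f}\t"
                f"{h.aligned_len}\t{h.mismatches}\t{h.gaps}\t"
                f"{h.q_span[0]}\t{h.q_span[1]}\t{h.r_span[0]}\t{h.r_span[1]}\t"
                f"{h.evalue:.3g}\t{h.score}\n"
            )
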