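"""Six-frame translation and ORF extraction.

Reads and contigs are translated in all six reading frames under the standard
genetic code (Cnidaria nuclear transcripts use it); stop codons render as
``*`` and codons containing ``N`` as ``X``.  ORFs run from an initiator Met to
the next stop (or to the end of the frame when no stop follows); nested ORFs
sharing a stop are collapsed to the longest one (most 5' Met).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

from Bio.Seq import Seq

from .seqio import NucRecord, ProtRecord

FRAMES = (1, 2, 3, -1, -2, -3)


def six_frame_translate(rec: NucRecord) -> Dict[int, ProtRecord]:
    """Translate a record in all six frames (keys +1..+3, -1..-3).

    Reverse frames translate the reverse complement; trailing 1-2 nt that do
    not fill a codon are dropped.  Requires a sequence of at least 3 nt.
    """
    if len(rec.seq) < 3:
        raise ValueError(f"sequence {rec.id!r} shorter than one codon")
    fwd = Seq(rec.seq)
    rev = fwd.reverse_complement()
    out: Dict[int, ProtRecord] = {}
    for frame in FRAMES:
        strand = fwd if frame > 0 else rev
        off = abs(frame) - 1
        usable = len(strand) - off
        usable -= usable % 3
        if usable < 3:
            continue
        aa = str(strand[off : off + usable].translate())
        out[frame] = ProtRecord(f"{rec.id}|frame{frame:+d}", aa)
    return out


@dataclass
class OrfCandidate:
    """An ORF located on a source nucleotide sequence.

    ``nt_start``/``nt_end`` are 0-based half-open coordinates on the *forward*
    strand of the source; when a terminating stop codon exists
    (``stop_seen``), the span includes it, so the span is always
    ``3 * (len(aa_seq) + stop_seen)`` nt.  ``aa_start`` is the Met's 0-based
    index within the frame translation.
    """

    source_id: str
    frame: int
    nt_start: int
    nt_end: int
    aa_seq: str
    stop_seen: bool
    aa_start: int = 0

    def __len__(self) -> int:
        return len(self.aa_seq)


def find_orfs(prot: ProtRecord, min_len_aa: int, frame: int = 1,
              source_id: str | None = None,
              source_nt_len: int | None = None) -> List[OrfCandidate]:
    """ORFs in one frame translation, Met to stop/end, longest per stop.

    ``frame`` and ``source_nt_len`` give the nucleotide coordinates meaning;
    when the translation is not tied to a nucleotide source, the defaults
    treat the protein itself as frame +1 of a 3*len source.
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    aa = prot.seq
    source_id = source_id if source_id is not None else prot.id
    nt_len = source_nt_len if source_nt_len is not None else 3 * len(aa)
    out: List[OrfCandidate] = []
    block_start = 0
    for block in aa.split("*"):
        stop_seen = block_start + len(block) < len(aa)
        m = block.find("M")
        if m >= 0:
            orf_aa = block[m:]
            if len(orf_aa) >= min_len_aa:
                aa_start = block_start + m
                aa_end = block_start + len(block) + (1 if stop_seen else 0)
                off = abs(frame) - 1
                s = off + 3 * aa_start
                e = off + 3 * aa_end
                if frame > 0:
                    nt_start, nt_end = s, e
                else:
                    nt_start, nt_end = nt_len - e, nt_len - s
                out.append(
                    OrfCandidate(
                        source_id=source_id,
                        frame=frame,
                        nt_start=nt_start,
                        nt_end=nt_end,
                        aa_seq=orf_aa,
                        stop_seen=stop_seen,
                        aa_start=aa_start,
                    )
                )
        block_start += len(block) + 1
    return out


def six_frame_orfs(rec: NucRecord, min_len_aa: int) -> List[OrfCandidate]:
    """All ORFs of length >= ``min_len_aa`` across the six frames."""
    out: List[OrfCandidate] = []
    for frame, prot in six_frame_translate(rec).items():
        out.extend(
            find_orfs(prot, min_len_aa, frame=frame, source_id=rec.id,
                      source_nt_len=len(rec.seq))
        )
    return out
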