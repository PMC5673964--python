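"""Desk-scale greedy overlap-consensus read assembly.

After homology binning, each structural group holds a small set of reads
drawn from a handful of transcripts; a transparent greedy overlap-layout-
consensus procedure is all that scale needs.  The assembler repeatedly
merges the fragment pair (considering both strands) with the longest
suffix-prefix overlap of at least ``min_overlap`` bases at ``min_identity``
or better, building the consensus by per-column majority over the member
reads (ties resolved toward the longer fragment's base).  Candidate overlaps
are proposed by shared ``seed_k``-mers and verified exactly, so the result
is identical to an exhaustive overlap scan whenever true overlaps contain at
least one exact seed (always, for substitution rates well below 1/seed_k).

Tie-breaks are canonical — longest overlap first, then the lexicographically
smallest member read ids — so the output is invariant to input order, and no
read is ever lost or duplicated across contigs.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .seqio import NucRecord

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_DEC = "ACGTN"
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


_ENC_TABLE = np.full(256, 4, dtype=np.uint8)
for _c, _v in _ENC.items():
    _ENC_TABLE[ord(_c)] = _v


def _encode(seq: str) -> np.ndarray:
    return _ENC_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode(arr: np.ndarray) -> str:
    return "".join(_DEC[b] for b in arr)


def _revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


@dataclass
class Contig:
    """An assembled consensus with full member provenance.

    ``members`` lists (read id, offset on the contig, strand); the depth
    profile counts member reads covering each consensus base.
    """

    id: str
    seq: str
    members: List[Tuple[str, int, str]]
    depth_profile: List[int]

    def __len__(self) -> int:
        return len(self.seq)


class _Frag:
    __slots__ = ("token", "key", "arr", "members", "kmers")

    def __init__(self, token: int, key: str, arr: np.ndarray,
                 members: List[Tuple[str, int, str]]):
        self.token = token
        self.key = key
        self.arr = arr
        self.members = members
        self.kmers: Optional[Dict[str, int]] = None  # kmer -> first position


def _frag_kmers(frag: _Frag, k: int) -> Dict[str, int]:
    if frag.kmers is None:
        s = _decode(frag.arr)
        km: Dict[str, int] = {}
        for i in range(len(s) - k + 1):
            km.setdefault(s[i : i + k], i)
        frag.kmers = km
    return frag.kmers


def _best_overlap(a: _Frag, b: _Frag, min_overlap: int, min_identity: float,
                  k: int) -> Optional[Tuple[int, int, int]]:
    """Best placement of b on a: (overlap_len, orient, shift) or None.

    orient 0 = b forward, 1 = b reverse-complemented; shift is b's offset on
    a's coordinates (may be negative).  Candidates come from shared k-mers;
    each is verified by exact column comparison over the implied overlap.
    """
    akm = _frag_kmers(a, k)
    best: Optional[Tuple[int, int, int]] = None
    la, lb = len(a.arr), len(b.arr)
    for orient, barr in ((0, b.arr), (1, _revcomp(b.arr))):
        shifts = set()
        bs = _decode(barr)
        for j in range(len(bs) - k + 1):
            i = akm.get(bs[j : j + k])
            if i is not None:
                shifts.add(i - j)
        for shift in shifts:
            lo = max(0, shift)
            hi = min(la, shift + lb)
            ovl = hi - lo
            if ovl < min_overlap:
                continue
            aseg = a.arr[lo:hi]
            bseg = barr[lo - shift : hi - shift]
            ident = float(np.mean(aseg == bseg))
            if ident < min_identity:
                continue
            cand = (ovl, orient, shift)
            if best is None or (cand[0], -cand[1], -cand[2]) > (
                best[0], -best[1], -best[2]
            ):
                best = cand
    return best


def assemble(reads: Sequence[NucRecord], min_overlap: int = 30,
             min_identity: float = 0.95, seed_k: int = 12) -> List[Contig]:
    """Greedy overlap-consensus assembly of a read set."""
    if min_overlap < 10:
        raise ValueError("min_overlap must be >= 10")
    if not (0.8 <= min_identity <= 1.0):
        raise ValueError("min_identity must be in [0.8, 1.0]")
    if not reads:
        return []
    read_arr = {}
    for r in sorted(reads, key=lambda r: r.id):
        if r.id in read_arr:
            raise ValueError(f"duplicate read id {r.id!r}")
        read_arr[r.id] = _encode(r.seq)

    frags: Dict[int, _Frag] = {}
    token_counter = 0
    for rid in sorted(read_arr):
        frags[token_counter] = _Frag(token_counter, rid, read_arr[rid],
                                     [(rid, 0, "+")])
        token_counter += 1

    k = seed_k
    heap: List[Tuple] = []

    def push_pairs(new_tokens, other_tokens):
        for ta in new_tokens:
            fa = frags[ta]
            for tb in other_tokens:
                if tb == ta or tb not in frags:
                    continue
                fb = frags[tb]
                a, b = (fa, fb) if fa.key < fb.key else (fb, fa)
                ovl = _best_overlap(a, b, min_overlap, min_identity, k)
                if ovl is not None:
                    olen, orient, shift = ovl
                    heapq.heappush(
                        heap,
                        (-olen, a.key, b.key, orient, shift, a.token, b.token),
                    )

    # candidate pairs via a global seed index (unrelated fragments are never
    # compared); verified overlaps go on the heap
    seed_index: Dict[str, List[int]] = {}
    candidate_pairs = set()
    for t, f in frags.items():
        for kmseq in _frag_kmers(f, k):
            seed_index.setdefault(kmseq, []).append(t)
        rc = _decode(_revcomp(f.arr))
        for j in range(len(rc) - k + 1):
            kmseq = rc[j : j + k]
            for t2 in seed_index.get(kmseq, ()):
                if t2 != t:
                    candidate_pairs.add((min(t, t2), max(t, t2)))
    for kmseq, toks in seed_index.items():
        if len(toks) > 1:
            for i in range(len(toks)):
                for j in range(i + 1, len(toks)):
                    candidate_pairs.add((toks[i], toks[j]))
    for ta, tb in sorted(candidate_pairs):
        push_pairs([ta], [tb])

    def merge(a: _Frag, b: _Frag, orient: int, shift: int) -> _Frag:
        nonlocal token_counter
        barr = b.arr if orient == 0 else _revcomp(b.arr)
        bmembers = b.members
        if orient == 1:
            lb = len(b.arr)
            bmembers = [
                (rid, lb - off - len(read_arr[rid]), "-" if st == "+" else "+")
                for rid, off, st in b.members
            ]
        origin = min(0, shift)
        length = max(len(a.arr), shift + len(barr)) - origin
        counts = np.zeros((length, 5), dtype=np.float64)
        members = []
        for rid, off, st in a.members:
            members.append((rid, off - origin, st))
        for rid, off, st in bmembers:
            members.append((rid, off + shift - origin, st))
        for rid, off, st in members:
            arr = read_arr[rid] if st == "+" else _revcomp(read_arr[rid])
            counts[np.arange(off, off + len(arr)), arr] += 1.0
        # majority ties resolve toward the longer input fragment's base
        longer = a if len(a.arr) >= len(barr) else b
        larr = longer.arr if (longer is a or orient == 0) else barr
        loff = (0 if longer is a else shift) - origin
        counts[np.arange(loff, loff + len(larr)), larr] += 0.4
        cons = np.argmax(counts, axis=1).astype(np.uint8)
        frag = _Frag(token_counter, min(a.key, b.key), cons,
                     sorted(members))
        token_counter += 1
        return frag

    while heap:
        negovl, keya, keyb, orient, shift, ta, tb = heapq.heappop(heap)
        if ta not in frags or tb not in frags:
            continue
        a, b = frags.pop(ta), frags.pop(tb)
        merged = merge(a, b, orient, shift)
        alive = list(frags.keys())
        frags[merged.token] = merged
        push_pairs([merged.token], alive)

    contigs = []
    for f in sorted(frags.values(), key=lambda f: f.key):
        depth = np.zeros(len(f.arr), dtype=int)
        for rid, off, st in f.members:
            depth[off : off + len(read_arr[rid])] += 1
        contigs.append(
            Contig(
                id=f"ctg_{f.key}",
                seq=_decode(f.arr),
                members=sorted(f.members),
                depth_profile=depth.tolist(),
            )
        )
    return contigs
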