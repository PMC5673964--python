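"""Precursor filtering, merging, nomenclature, and overlap reports.

The four-rule precursor filter keeps an ORF only when it (1) is at least 50
aa long, (2) contains no early termination signal (an internal stop within
the precursor span), (3) has no long amino-acid repeat, and (4) carries a
predicted signal peptide.  Rejected candidates are retained with audit flags
(the first failing rule, in order 1-4, is the primary reason).

Candidates surviving from the three search strategies are merged on
identical mature sequences, the per-method overlap (Venn regions) is
reported, and surviving molecules are named by class: ``AnmTX`` anemone
neurotoxins (known structural group + qualifying toxin homology), ``CjTL``
toxin-like peptides (novel or linear framework, mature < 60 aa), ``CjPP``
longer polypeptides without homology, and ``CjVP`` venom proteins
(precursor >= 200 aa).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .frameworks import (CysFramework, FrameworkRegistry, classify,
                         extract_framework, format_motif)
from .seqio import ProtRecord
from .signalpep import SignalCall, SignalParams, score_signal

FILTER_RULES = ("short", "early_stop", "repeat", "no_signal")


def has_long_repeat(seq: str, max_repeat: int = 5) -> bool:
    """More than ``max_repeat`` consecutive amino-acid repeats.

    Covers both readings of a "more than 5 amino acid repeats" rule: a single
    residue occurring more than ``max_repeat`` times in a row, or a unit of
    length 2-5 tandemly repeated more than ``max_repeat`` times.
    """
    n = len(seq)
    run = 1
    for i in range(1, n):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        if run > max_repeat:
            return True
    for unit in range(2, 6):
        limit = unit * (max_repeat + 1)
        if n < limit:
            continue
        for start in range(n - limit + 1):
            reps = 1
            while (
                start + (reps + 1) * unit <= n
                and seq[start + reps * unit : start + (reps + 1) * unit]
                == seq[start : start + unit]
            ):
                reps += 1
                if reps > max_repeat:
                    return True
    return False


@dataclass
class PrecursorCandidate:
    """A candidate toxin precursor with provenance and audit flags."""

    id: str
    precursor: ProtRecord
    methods: Set[int] = field(default_factory=set)
    group_bin: Optional[str] = None
    signal: Optional[SignalCall] = None
    mature: Optional[ProtRecord] = None
    framework: Optional[CysFramework] = None
    framework_label: Optional[str] = None
    flags: Dict[str, bool] = field(default_factory=dict)
    passed: bool = False
    primary_flag: Optional[str] = None
    source_id: Optional[str] = None
    source_members: Optional[List[str]] = None


def _annotate(cand: PrecursorCandidate, sig_params: SignalParams,
              registry: Optional[FrameworkRegistry]) -> None:
    cand.signal = score_signal(cand.precursor, sig_params)
    if cand.signal.present:
        mature_seq = cand.precursor.seq[cand.signal.cleavage_pos :]
    else:
        mature_seq = cand.precursor.seq
    if mature_seq and "*" not in mature_seq:
        cand.mature = ProtRecord(cand.id + "|mature", mature_seq)
        cand.framework = extract_framework(mature_seq)
        if registry is not None:
            cand.framework_label = classify(mature_seq, registry)


def filter3(precursors: Sequence, min_len_aa: int = 50, max_repeat: int = 5,
            sig_params: SignalParams = SignalParams(),
            registry: Optional[FrameworkRegistry] = None,
            method: Optional[int] = None,
            group_bin: Optional[str] = None) -> List[PrecursorCandidate]:
    """Apply the four-rule precursor filter with full audit flags.

    ``precursors`` may be ProtRecords or any objects with ``id``/``seq``
    (e.g. ORF-derived records).  Every input yields a candidate; survivors
    have ``passed=True``, rejections carry the first failing rule in
    ``primary_flag``.  Output order follows input order.
    """
    out: List[PrecursorCandidate] = []
    for rec in precursors:
        seq = rec.seq if hasattr(rec, "seq") else rec.aa_seq
        rid = rec.id if hasattr(rec, "id") else rec.source_id
        prot = ProtRecord(rid, seq)
        cand = PrecursorCandidate(
            id=rid,
            precursor=prot,
            methods={method} if method else set(),
            group_bin=group_bin,
            source_id=getattr(rec, "source_id", None),
        )
        _annotate(cand, sig_params, registry)
        core = seq[:-1] if seq.endswith("*") else seq
        cand.flags["short"] = len(core) < min_len_aa
        cand.flags["early_stop"] = "*" in core
        cand.flags["repeat"] = not cand.flags["early_stop"] and has_long_repeat(
            core, max_repeat
        )
        cand.flags["no_signal"] = not (cand.signal and cand.signal.present)
        cand.passed = not any(cand.flags.values())
        cand.primary_flag = next(
            (rule for rule in FILTER_RULES if cand.flags[rule]), None
        )
        out.append(cand)
    return out


def make_candidate(rec, method: int, sig_params: SignalParams = SignalParams(),
                   registry: Optional[FrameworkRegistry] = None,
                   group_bin: Optional[str] = None,
                   source_id: Optional[str] = None) -> PrecursorCandidate:
    """An annotated, unfiltered candidate (methods 1-2 skip the filter)."""
    seq = rec.seq if hasattr(rec, "seq") else rec.aa_seq
    seq = seq[:-1] if seq.endswith("*") else seq
    cand = PrecursorCandidate(
        id=rec.id if hasattr(rec, "id") else rec.source_id,
        precursor=ProtRecord(rec.id if hasattr(rec, "id") else rec.source_id, seq),
        methods={method},
        group_bin=group_bin,
        source_id=source_id,
    )
    _annotate(cand, sig_params, registry)
    cand.passed = True
    return cand


def merge_methods(per_method: Dict[int, Sequence[PrecursorCandidate]]
                  ) -> List[PrecursorCandidate]:
    """Merge per-method candidate sets on identical mature sequences.

    The merged candidate keeps the annotation of its first occurrence (method
    order, then input order) and the union of method memberships.
    """
    merged: Dict[str, PrecursorCandidate] = {}
    for method in sorted(per_method):
        for cand in per_method[method]:
            key = cand.mature.seq if cand.mature else cand.precursor.seq
            if key in merged:
                merged[key].methods |= cand.methods or {method}
                if merged[key].group_bin is None:
                    merged[key].group_bin = cand.group_bin
            else:
                cand.methods = set(cand.methods) or {method}
                merged[key] = cand
    return list(merged.values())


def venn_counts(cands: Sequence[PrecursorCandidate],
                methods: Sequence[int] = (1, 2, 3)) -> Dict[str, int]:
    """Counts per method-overlap region; keys like '1', '1&3', '1&2&3'."""
    counts: Dict[str, int] = {}
    for r in range(1, len(methods) + 1):
        for combo in itertools.combinations(methods, r):
            counts["&".join(map(str, combo))] = 0
    for cand in cands:
        key = "&".join(map(str, sorted(cand.methods)))
        if key in counts:
            counts[key] += 1
    return counts


@dataclass
class NamedToxin:
    candidate: PrecursorCandidate
    name: str
    toxin_class: str  # AnmTX | CjTL | CjPP | CjVP


def assign_names(cands: Sequence[PrecursorCandidate],
                 registry: FrameworkRegistry,
                 homology: Optional[Dict[str, float]] = None,
                 species_tag: str = "Cj",
                 anmtx_emax: float = 1e-3,
                 cjtl_max_mature: int = 60,
                 cjvp_min_precursor: int = 200) -> List[NamedToxin]:
    """Assign nomenclature to surviving candidates, in input order.

    ``homology`` maps candidate id to its best toxin-database E-value (absent
    = no hit).  Anemone neurotoxins (AnmTX) need a named structural group and
    a hit at E <= ``anmtx_emax`` and are numbered within each group; the
    remaining classes get running indices.
    """
    homology = homology or {}
    named: List[NamedToxin] = []
    group_counters: Dict[str, int] = {}
    tl_counter = pp_counter = vp_counter = 0
    for cand in cands:
        label = cand.framework_label or (
            classify(cand.mature.seq, registry) if cand.mature else "new"
        )
        best_e = homology.get(cand.id)
        mature_len = len(cand.mature.seq) if cand.mature else len(cand.precursor.seq)
        if len(cand.precursor.seq) >= cjvp_min_precursor:
            vp_counter += 1
            named.append(NamedToxin(cand, f"{species_tag}VP{vp_counter}", "CjVP"))
        elif (label not in ("new", "linear") and best_e is not None
              and best_e <= anmtx_emax):
            group_counters[label] = group_counters.get(label, 0) + 1
            named.append(
                NamedToxin(
                    cand,
                    f"AnmTX {species_tag} {label}-{group_counters[label]}",
                    "AnmTX",
                )
            )
        elif mature_len < cjtl_max_mature:
            tl_counter += 1
            named.append(NamedToxin(cand, f"{species_tag}TL{tl_counter}", "CjTL"))
        else:
            pp_counter += 1
            named.append(NamedToxin(cand, f"{species_tag}PP{pp_counter}", "CjPP"))
    return named


# ---------------------------------------------------------------------------
# Candidate table IO ('#'-prefixed header, UTF-8 TSV)

_COLUMNS = ("id", "method", "group", "precursor", "signal_end", "mature",
            "framework", "flags", "passed")


def write_candidates(cands: Sequence[PrecursorCandidate], path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(_COLUMNS) + "\n")
        for c in cands:
            flags = ";".join(rule for rule in FILTER_RULES if c.flags.get(rule))
            fh.write(
                "\t".join(
                    [
                        c.id,
                        ",".join(map(str, sorted(c.methods))) or "-",
                        c.group_bin or "-",
                        c.precursor.seq,
                        str(c.signal.cleavage_pos)
                        if c.signal and c.signal.present
                        else "-",
                        c.mature.seq if c.mature else "-",
                        format_motif(c.framework) if c.framework else "-",
                        flags or "-",
                        "1" if c.passed else "0",
                    ]
                )
                + "\n"
            )


def read_candidates(path) -> List[PrecursorCandidate]:
    cands: List[PrecursorCandidate] = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"candidate table {path} lacks a '#' header")
    for line in lines[1:]:
        if not line.strip():
            continue
        (cid, methods, group, precursor, signal_end, mature, framework,
         flags, passed) = line.split("\t")
        cand = PrecursorCandidate(
            id=cid,
            precursor=ProtRecord(cid, precursor),
            methods=set(int(m) for m in methods.split(",")) if methods != "-" else set(),
            group_bin=None if group == "-" else group,
        )
        if signal_end != "-":
            cand.signal = SignalCall(present=True, cleavage_pos=int(signal_end))
        else:
            cand.signal = SignalCall(present=False)
        if mature != "-":
            cand.mature = ProtRecord(cid + "|mature", mature)
            cand.framework = extract_framework(mature)
        cand.flags = {rule: False for rule in FILTER_RULES}
        if flags != "-":
            for rule in flags.split(";"):
                cand.flags[rule] = True
        cand.passed = passed == "1"
        cand.primary_flag = next(
            (rule for rule in FILTER_RULES if cand.flags[rule]), None
        )
        cands.append(cand)
    return cands
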