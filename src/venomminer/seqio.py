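"""Sequence records and FASTA/FASTQ input/output.

The pipeline's currency is two small record types: :class:`NucRecord` for DNA
(reads, transcripts, contigs) and :class:`ProtRecord` for amino-acid sequences
(reference toxins, translated frames, precursors).  Parsing is delegated to
:mod:`Bio.SeqIO`; on top of that we apply the normalisation rules the rest of
the pipeline relies on: sequences are uppercased, ``U`` is mapped to ``T`` in
nucleotide input (RNA-style exports), and any other unexpected nucleotide
letter becomes ``N``.  Record ids are the pre-whitespace header token; the full
header is retained as the description.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

from Bio import SeqIO

NUC_ALPHABET = set("ACGTN")
# 20 standard residues plus '*' (stop, as produced by translation) and 'X'.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
PROT_ALPHABET = set(AA20) | {"*", "X"}

_NUC_TRANS = {c: c for c in "ACGTN"}
_NUC_TRANS["U"] = "T"


def _clean_nuc(seq: str) -> str:
    up = seq.upper()
    return "".join(_NUC_TRANS.get(c, "N") for c in up)


def _clean_prot(seq: str) -> str:
    up = seq.upper()
    return "".join(c if c in PROT_ALPHABET else "X" for c in up)


@dataclass
class NucRecord:
    """A named DNA sequence, optionally with Phred quality scores."""

    id: str
    seq: str
    qual: Optional[List[int]] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"quality length {len(self.qual)} != sequence length "
                f"{len(self.seq)} for record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "NucRecord":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        rc = "".join(comp[c] for c in reversed(self.seq))
        qual = list(reversed(self.qual)) if self.qual is not None else None
        return NucRecord(self.id, rc, qual=qual, description=self.description)


@dataclass
class ProtRecord:
    """A named amino-acid sequence over the 20 residues plus '*' and 'X'."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ObservedPeptide:
    """One piece of peptide-level evidence from the venom proteome.

    Either the full peptide sequence, its monoisotopic mass (Da), or both must
    be present; this abstracts the identification layer of an LC-MS/MS run.
    """

    source_id: str
    seq: Optional[str] = None
    mono_mass: Optional[float] = None

    def __post_init__(self) -> None:
        if self.seq is None and self.mono_mass is None:
            raise ValueError(
                f"observed peptide {self.source_id!r} needs a sequence or a mass"
            )
        if self.mono_mass is not None and self.mono_mass <= 0:
            raise ValueError(
                f"observed peptide {self.source_id!r} has non-positive mass"
            )


def _check_unique_ids(records: Sequence) -> None:
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)


def read_fasta(path, kind: str = "nuc"):
    """Read a FASTA file into Nuc/ProtRecords (``kind`` = 'nuc' or 'prot').

    Raises on an empty file and on duplicate ids (naming the offender).
    """
    if kind not in ("nuc", "prot"):
        raise ValueError(f"kind must be 'nuc' or 'prot', got {kind!r}")
    records = []
    for sr in SeqIO.parse(str(path), "fasta"):
        seq = str(sr.seq)
        if kind == "nuc":
            records.append(
                NucRecord(sr.id, _clean_nuc(seq), description=sr.description)
            )
        else:
            records.append(
                ProtRecord(sr.id, _clean_prot(seq), description=sr.description)
            )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    _check_unique_ids(records)
    return records


def read_fastq(path) -> List[NucRecord]:
    """Read Phred+33 FASTQ; an empty file yields an empty list."""
    records = []
    for sr in SeqIO.parse(str(path), "fastq"):
        records.append(
            NucRecord(
                sr.id,
                _clean_nuc(str(sr.seq)),
                qual=list(sr.letter_annotations["phred_quality"]),
                description=sr.description,
            )
        )
    _check_unique_ids(records)
    return records


def write_fasta(records: Iterable, path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_fastq(records: Iterable[NucRecord], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None else [40] * len(rec.seq)
            qstr = "".join(chr(q + 33) for q in qual)
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f"@{header}\n{rec.seq}\n+\n{qstr}\n")
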