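"""Proteogenomic validation against tryptic-peptide evidence.

Transcriptome-predicted precursors are confirmed by the venom proteome: the
predicted proteins are digested in silico with trypsin (cleavage C-terminal
to K/R except before P), observed peptides are matched to the digest either
by exact sequence or by monoisotopic mass within a ppm tolerance, and a
precursor is *validated* when at least two distinct peptides match it.
Coverage is the fraction of the precursor covered by the union of matched
peptide spans.

Cysteines are carbamidomethylated as a fixed modification (iodoacetamide
treatment before digestion), adding 57.021464 Da per Cys when enabled.
Monoisotopic residue masses come from pyteomics' standard table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from pyteomics import mass as _pymass

from .seqio import ObservedPeptide, ProtRecord

WATER_MONO = 18.010565
CARBAMIDOMETHYL = 57.021464

# restricted to the 20 standard residues (no B/J/O/U/X/Z ambiguity codes)
_RESIDUE_MASS: Dict[str, float] = {
    aa: _pymass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}


@dataclass
class TrypticPeptide:
    seq: str
    protein_id: str
    span: Tuple[int, int]  # 0-based half-open on the precursor
    missed: int
    mono_mass: float


def mono_mass(pep: str, cys_fixed_mod: bool = False) -> float:
    """Monoisotopic peptide mass in Da (residues + water, optional Cys mod)."""
    if not pep:
        raise ValueError("empty peptide")
    total = WATER_MONO
    for c in pep:
        try:
            total += _RESIDUE_MASS[c]
        except KeyError:
            raise ValueError(f"unknown residue {c!r} in peptide {pep!r}") from None
    if cys_fixed_mod:
        total += CARBAMIDOMETHYL * pep.count("C")
    return total


def tryptic_digest(prot, max_missed: int = 0,
                   cys_fixed_mod: bool = False) -> List[TrypticPeptide]:
    """In-silico trypsin digest with up to ``max_missed`` missed cleavages.

    Cleaves after K or R unless the next residue is P.  With max_missed=0 the
    peptides partition the protein.
    """
    seq = prot.seq if hasattr(prot, "seq") else str(prot)
    pid = prot.id if hasattr(prot, "id") else "protein"
    if "*" in seq:
        raise ValueError(f"stop symbol in {pid!r}; digest mature proteins only")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    cut_after = [
        i for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    bounds = [0] + [i + 1 for i in cut_after] + [len(seq)]
    peptides: List[TrypticPeptide] = []
    n_base = len(bounds) - 1
    for i in range(n_base):
        for missed in range(0, max_missed + 1):
            j = i + missed + 1
            if j > n_base:
                break
            lo, hi = bounds[i], bounds[j]
            pep = seq[lo:hi]
            peptides.append(
                TrypticPeptide(
                    seq=pep,
                    protein_id=pid,
                    span=(lo, hi),
                    missed=missed,
                    mono_mass=mono_mass(pep, cys_fixed_mod),
                )
            )
    return peptides


@dataclass
class PeptideMatch:
    source_id: str
    peptide: str
    span: Tuple[int, int]
    mode: str                      # "sequence" or "mass"
    ppm_error: Optional[float] = None


@dataclass
class ValidationReport:
    protein_id: str
    n_distinct_peptides: int
    coverage: float
    validated: bool
    matched: List[PeptideMatch] = field(default_factory=list)


def match_evidence(obs: Sequence[ObservedPeptide], preds: Sequence,
                   tol_ppm: float = 10.0, max_missed: int = 1,
                   cys_fixed_mod: bool = True,
                   min_distinct: int = 2) -> List[ValidationReport]:
    """Match observed peptides to predicted precursors and validate.

    ``preds`` holds ProtRecords or candidates exposing ``.precursor``.
    Sequence-bearing observations match by exact equality to a predicted
    tryptic peptide; mass-only observations match any predicted peptide
    within ``tol_ppm``.  A protein is validated when at least ``min_distinct``
    distinct peptide sequences match it.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    reports: List[ValidationReport] = []
    for pred in preds:
        prot = pred.precursor if hasattr(pred, "precursor") else pred
        peptides = tryptic_digest(prot, max_missed=max_missed,
                                  cys_fixed_mod=cys_fixed_mod)
        matches: List[PeptideMatch] = []
        for ob in obs:
            for pep in peptides:
                if ob.seq is not None:
                    if ob.seq == pep.seq:
                        matches.append(
                            PeptideMatch(ob.source_id, pep.seq, pep.span,
                                         "sequence")
                        )
                        break
                elif ob.mono_mass is not None:
                    ppm = (ob.mono_mass - pep.mono_mass) / pep.mono_mass * 1e6
                    if abs(ppm) <= tol_ppm:
                        matches.append(
                            PeptideMatch(ob.source_id, pep.seq, pep.span,
                                         "mass", ppm_error=ppm)
                        )
                        break
        distinct = sorted({m.peptide for m in matches})
        covered = set()
        for m in matches:
            covered.update(range(*m.span))
        coverage = len(covered) / len(prot.seq)
        reports.append(
            ValidationReport(
                protein_id=prot.id,
                n_distinct_peptides=len(distinct),
                coverage=coverage,
                validated=len(distinct) >= min_distinct,
                matched=matches,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# Evidence and report tables


def read_observed_tsv(path) -> List[ObservedPeptide]:
    """TSV with columns peptide, mass, source_id (either of the first two
    may be empty)."""
    out: List[ObservedPeptide] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        pep, mass_s, source = (line.split("\t") + ["", "", ""])[:3]
        out.append(
            ObservedPeptide(
                source_id=source or f"obs{len(out) + 1}",
                seq=pep or None,
                mono_mass=float(mass_s) if mass_s else None,
            )
        )
    return out


def write_observed_tsv(obs: Sequence[ObservedPeptide], path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("#peptide\tmass\tsource_id\n")
        for ob in obs:
            fh.write(
                f"{ob.seq or ''}\t"
                f"{'' if ob.mono_mass is None else f'{ob.mono_mass:.6f}'}\t"
                f"{ob.source_id}\n"
            )


def write_reports_tsv(reports: Sequence[ValidationReport], path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("#protein\tn_peptides\tcoverage\tvalidated\tpeptides\n")
        for r in reports:
            peps = ";".join(sorted({m.peptide for m in r.matched}))
            fh.write(
                f"{r.protein_id}\t{r.n_distinct_peptides}\t{r.coverage:.4f}\t"
                f"{int(r.validated)}\t{peps or '-'}\n"
            )
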