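"""The cysteine-framework mini-language.

Sea anemone venom peptides are classified into structural groups by their
*Cys framework*: the ordered pattern of cysteine residues and the lengths of
the spacers between them, written as a motif string such as ``C8C3C11C5CC6``
(read: Cys, 8 residues, Cys, 3 residues, Cys, 11 residues, Cys, 5 residues,
Cys, Cys, 6 trailing residues).  This module formalises that notation as a
small grammar, computes its arithmetic (span, cysteine count), extracts the
framework realised by a concrete mature peptide, matches sequences against
patterns, and classifies peptides against a registry of named structural
groups — flagging frameworks that match no known group as ``"new"``.

Grammar (after normalisation):

* ``C`` — a cysteine.
* an integer ``n`` between two C's — a spacer of exactly ``n`` residues.
* ``[a-b]`` — a spacer of between ``a`` and ``b`` residues.
* ``#`` — a spacer of unspecified length (at least 1); ``##`` therefore means
  a gap of at least 2.
* adjacent ``CC`` — vicinal cysteines (spacer of exactly 0).
* digits after the final C — an exact trailing flank; digits before the first
  C — an exact leading flank.

Published motif strings mix the Cyrillic letter ``С`` with the Latin ``C``,
en-dashes with hyphens, and use decorative hyphens around spacer numbers
(``C8C-3-C11C-5-CC6``); :func:`normalize_motif` folds all of these away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union


# ---------------------------------------------------------------------------
# Spacer terms


@dataclass(frozen=True)
class Exact:
    n: int

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("Exact spacer must be >= 0")

    bounds = property(lambda self: (self.n, self.n))

    def __str__(self) -> str:
        return str(self.n) if self.n else ""


@dataclass(frozen=True)
class Range:
    a: int
    b: int

    def __post_init__(self) -> None:
        if not (0 <= self.a < self.b):
            raise ValueError(f"Range requires 0 <= a < b, got [{self.a}-{self.b}]")

    bounds = property(lambda self: (self.a, self.b))

    def __str__(self) -> str:
        return f"[{self.a}-{self.b}]"


@dataclass(frozen=True)
class Open:
    """A spacer of unspecified length, at least 1 residue."""

    bounds = property(lambda self: (1, None))

    def __str__(self) -> str:
        return "#"


SpacerTerm = Union[Exact, Range, Open]


def _terms_bounds(terms: Optional[List[SpacerTerm]]) -> Tuple[int, Optional[int]]:
    """Sum the (min, max) bounds of a list of spacer terms; absent -> (0, 0)."""
    if not terms:
        return (0, 0)
    lo = sum(t.bounds[0] for t in terms)
    hi: Optional[int] = 0
    for t in terms:
        b = t.bounds[1]
        if b is None or hi is None:
            hi = None
        else:
            hi += b
    return (lo, hi)


def _in_bounds(length: int, terms: Optional[List[SpacerTerm]]) -> bool:
    lo, hi = _terms_bounds(terms)
    return length >= lo and (hi is None or length <= hi)


# ---------------------------------------------------------------------------
# Frameworks


@dataclass(frozen=True)
class CysFramework:
    """A parsed cysteine-framework motif.

    ``gaps[i]`` is the list of spacer terms between the i-th and (i+1)-th
    cysteine (a gap may hold several terms: ``##`` contributes two Open terms
    whose lengths sum).  ``leading``/``trailing`` are flank term lists or
    ``None`` when the motif leaves the flank unconstrained.  ``leading_offset``
    records, for frameworks extracted from a concrete sequence, how many
    residues preceded the first cysteine; it is not part of the canonical
    motif string (published motifs begin at the first Cys).
    """

    n_cys: int
    gaps: Tuple[Tuple[SpacerTerm, ...], ...] = ()
    leading: Optional[Tuple[SpacerTerm, ...]] = None
    trailing: Optional[Tuple[SpacerTerm, ...]] = None
    leading_offset: int = 0

    def __post_init__(self) -> None:
        if self.n_cys < 0:
            raise ValueError("n_cys must be >= 0")
        if self.n_cys and len(self.gaps) != self.n_cys - 1:
            raise ValueError(
                f"{self.n_cys} cysteines need {self.n_cys - 1} gaps, "
                f"got {len(self.gaps)}"
            )

    @property
    def is_linear(self) -> bool:
        return self.n_cys == 0

    def specificity_terms(self) -> int:
        """Number of Range/Open terms (fewer = more specific pattern)."""
        count = 0
        for terms in self.gaps:
            count += sum(1 for t in terms if not isinstance(t, Exact))
        for flank in (self.leading, self.trailing):
            if flank:
                count += sum(1 for t in flank if not isinstance(t, Exact))
        return count


#: The distinguished framework of a cysteine-free (linear) peptide.
LINEAR = CysFramework(n_cys=0)


# ---------------------------------------------------------------------------
# Normalisation and parsing

_CYRILLIC_ES_UPPER = "С"
_CYRILLIC_ES_LOWER = "с"
_DASHES = {"–", "—", "−"}  # en-dash, em-dash, minus sign
_ALLOWED = set("C0123456789#[]-")


def normalize_motif(s: str) -> str:
    """Fold a published motif string onto the canonical grammar alphabet.

    Cyrillic ``С`` becomes Latin ``C``, en-dashes become hyphens, decorative
    hyphens outside ``[a-b]`` ranges are dropped, and whitespace is stripped.
    Any character outside the motif alphabet raises a ``ValueError`` naming it.
    """
    if not s:
        raise ValueError("empty motif string")
    out = []
    depth = 0
    for ch in s:
        if ch.isspace():
            continue
        if ch in (_CYRILLIC_ES_UPPER, _CYRILLIC_ES_LOWER) or ch == "c":
            ch = "C"
        if ch in _DASHES:
            ch = "-"
        if ch not in _ALLOWED:
            raise ValueError(f"invalid character {ch!r} in motif {s!r}")
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced ']' in motif {s!r}")
        elif ch == "-" and depth == 0:
            continue  # decorative hyphen
        out.append(ch)
    if depth != 0:
        raise ValueError(f"unclosed '[' in motif {s!r}")
    return "".join(out)


def _tokenize(s: str) -> List[Union[str, SpacerTerm]]:
    tokens: List[Union[str, SpacerTerm]] = []
    i = 0
    while i < len(s):
        ch = s[i]
        if ch == "C":
            tokens.append("C")
            i += 1
        elif ch.isdigit():
            j = i
            while j < len(s) and s[j].isdigit():
                j += 1
            tokens.append(Exact(int(s[i:j])))
            i = j
        elif ch == "#":
            tokens.append(Open())
            i += 1
        elif ch == "[":
            j = s.find("]", i)
            if j < 0:
                raise ValueError(f"unclosed bracket in motif {s!r}")
            body = s[i + 1 : j]
            if "-" not in body:
                raise ValueError(f"range without '-' in motif {s!r}")
            a_str, b_str = body.split("-", 1)
            if not (a_str.isdigit() and b_str.isdigit()):
                raise ValueError(f"malformed range [{body}] in motif {s!r}")
            a, b = int(a_str), int(b_str)
            if a >= b:
                raise ValueError(f"range [{a}-{b}] needs a < b in motif {s!r}")
            tokens.append(Range(a, b))
            i = j + 1
        else:
            raise ValueError(f"unexpected character {ch!r} in motif {s!r}")
    return tokens


def parse_motif(s: str) -> CysFramework:
    """Parse a (normalised) motif string into a :class:`CysFramework`."""
    s = normalize_motif(s)
    tokens = _tokenize(s)
    n_cys = sum(1 for t in tokens if t == "C")
    if n_cys == 0:
        raise ValueError(f"motif {s!r} contains no cysteine")
    # split on C's
    segments: List[List[SpacerTerm]] = [[]]
    for tok in tokens:
        if tok == "C":
            segments.append([])
        else:
            segments[-1].append(tok)
    leading = tuple(segments[0]) or None
    trailing = tuple(segments[-1]) or None
    gaps = []
    for seg in segments[1:-1]:
        gaps.append(tuple(seg) if seg else (Exact(0),))
    return CysFramework(
        n_cys=n_cys, gaps=tuple(gaps), leading=leading, trailing=trailing
    )


def format_motif(fw: CysFramework) -> str:
    """Canonical motif string of a framework (leading offset omitted)."""
    if fw.is_linear:
        return "linear"
    parts = []
    if fw.leading:
        parts.append("".join(str(t) for t in fw.leading))
    parts.append("C")
    for terms in fw.gaps:
        parts.append("".join(str(t) for t in terms))
        parts.append("C")
    if fw.trailing:
        parts.append("".join(str(t) for t in fw.trailing))
    return "".join(parts)


# ---------------------------------------------------------------------------
# Arithmetic


def span(fw: CysFramework) -> Tuple[int, Optional[int]]:
    """(min, max) realised length of a framework; ``None`` max = unbounded.

    Counts the cysteines, the spacer bounds, and the bounds of *explicit*
    flank terms; an absent flank contributes nothing (matching treats it as
    unconstrained instead).
    """
    lo = fw.n_cys
    hi: Optional[int] = fw.n_cys
    for terms in list(fw.gaps) + [fw.leading or (), fw.trailing or ()]:
        t_lo, t_hi = _terms_bounds(list(terms) or None)
        lo += t_lo
        hi = None if (hi is None or t_hi is None) else hi + t_hi
    return (lo, hi)


def cys_count(fw: CysFramework) -> int:
    return fw.n_cys


# ---------------------------------------------------------------------------
# Extraction, matching, classification


def _seq_of(mature) -> str:
    seq = mature.seq if hasattr(mature, "seq") else str(mature)
    if "*" in seq:
        raise ValueError("mature peptide must not contain a stop symbol")
    return seq


def extract_framework(mature) -> CysFramework:
    """The exact framework realised by a mature peptide.

    Cysteine-free sequences yield :data:`LINEAR`.  The canonical string runs
    from the first to the last Cys plus an exact trailing flank; residues
    before the first Cys are recorded in ``leading_offset``.
    """
    seq = _seq_of(mature)
    positions = [i for i, c in enumerate(seq) if c == "C"]
    if not positions:
        return LINEAR
    gaps = tuple(
        (Exact(positions[i + 1] - positions[i] - 1),)
        for i in range(len(positions) - 1)
    )
    return CysFramework(
        n_cys=len(positions),
        gaps=gaps,
        leading=None,
        trailing=(Exact(len(seq) - 1 - positions[-1]),),
        leading_offset=positions[0],
    )


def matches(mature, pattern: CysFramework) -> bool:
    """True iff the peptide's cysteine positions realise the pattern.

    Spacer lengths must fall within each gap's bounds; leading/trailing flank
    constraints apply only when the pattern states them (an absent flank term
    is unconstrained).
    """
    seq = _seq_of(mature)
    positions = [i for i, c in enumerate(seq) if c == "C"]
    if pattern.is_linear:
        return not positions
    if len(positions) != pattern.n_cys:
        return False
    for i, terms in enumerate(pattern.gaps):
        gap = positions[i + 1] - positions[i] - 1
        if not _in_bounds(gap, list(terms)):
            return False
    if pattern.leading is not None and not _in_bounds(
        positions[0], list(pattern.leading)
    ):
        return False
    if pattern.trailing is not None and not _in_bounds(
        len(seq) - 1 - positions[-1], list(pattern.trailing)
    ):
        return False
    return True


class FrameworkRegistry(dict):
    """Ordered mapping of structural-group label -> framework pattern.

    The label ``"linear"`` is reserved for cysteine-free peptides and is
    special-cased by :func:`classify`.
    """

    @classmethod
    def from_pairs(cls, pairs) -> "FrameworkRegistry":
        reg = cls()
        for label, motif in pairs:
            if label in reg:
                raise ValueError(f"duplicate registry label {label!r}")
            if label == "linear":
                reg[label] = LINEAR
            else:
                reg[label] = parse_motif(motif) if isinstance(motif, str) else motif
        return reg


def load_registry(path=None) -> FrameworkRegistry:
    """Load a registry from ``label<TAB>motif`` lines.

    ``#`` starts a comment only at the beginning of a line (inside a motif the
    character is a meaningful spacer term).  Without a path, the packaged
    default registry of named sea anemone structural groups is loaded.
    """
    if path is None:
        text = (
            resources.files("venomminer.data")
            .joinpath("frameworks.tsv")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    pairs = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ValueError(f"registry line needs 'label<TAB>motif': {line!r}")
        label, motif = fields[0].strip(), fields[1].strip()
        pairs.append((label, "C" if label == "linear" else motif))
    return FrameworkRegistry.from_pairs(pairs)


def classify(mature, registry: FrameworkRegistry) -> str:
    """Structural-group label of a mature peptide, or ``"new"``.

    Cys-free peptides are ``"linear"``.  Otherwise the unique matching
    registry pattern wins; with several matches the most specific pattern
    (fewest Range/Open terms) is chosen, ties broken lexicographically by
    label.  No match means a novel cysteine-distribution motif: ``"new"``.
    """
    seq = _seq_of(mature)
    if "C" not in seq:
        return "linear"
    hits = [
        (fw.specificity_terms(), label)
        for label, fw in registry.items()
        if label != "linear" and matches(seq, fw)
    ]
    if not hits:
        return "new"
    return min(hits)[1]
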