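"""Core data model for LTR retroelement annotation.

Coordinates are 0-based half-open everywhere inside the package; conversion to
the 1-based inclusive GFF3 convention happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

__all__ = [
    "LtrKitError",
    "FormatError",
    "ValidationError",
    "Strand",
    "Group",
    "RepeatMode",
    "GenomeSequence",
    "Interval",
    "DomainHit",
    "ElementAnnotation",
]


class LtrKitError(Exception):
    """Base class for all package errors."""


class FormatError(LtrKitError):
    """Malformed input file (FASTA/GFF3/BED/TSV)."""


class ValidationError(LtrKitError):
    """Domain-object invariant violated."""


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"
    UNSTRANDED = "."


class Group(str, Enum):
    BEL = "BEL"
    COPIA = "copia"
    DIRS = "DIRS"
    GYPSY = "gypsy"
    UNCLASSIFIED = "unclassified"

    @property
    def letter(self) -> str:
        return _GROUP_LETTER[self]


_GROUP_LETTER = {
    Group.BEL: "B",
    Group.COPIA: "C",
    Group.DIRS: "D",
    Group.GYPSY: "G",
}

LETTER_TO_GROUP = {v: k for k, v in _GROUP_LETTER.items()}


class RepeatMode(str, Enum):
    DIRECT = "direct"
    INVERTED = "inverted"


_DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomeSequence:
    """One scaffold: an identifier and its normalized DNA residues.

    Residues are uppercase over {A, C, G, T, N}; normalization (case folding,
    U->T, other ambiguity codes -> N) is performed by :func:`ltrkit.io.read_fasta`.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("scaffold id must be non-empty")
        if len(self.residues) < 1:
            raise ValidationError(f"scaffold {self.id!r}: empty sequence")
        bad = set(self.residues) - _DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"scaffold {self.id!r}: residues outside ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval [start, end) on a named scaffold."""

    scaffold: str
    start: int
    end: int
    strand: Strand = Strand.UNSTRANDED

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "Interval") -> int:
        if self.scaffold != other.scaffold:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class DomainHit:
    """A retained protein-domain alignment inside an element's internal region.

    ``frame`` is +1..+3 / -1..-3 relative to the sequence the ORF scan ran on;
    ``score`` is a raw local-alignment score in substitution-matrix units.
    """

    name: str  # GAG, PR, RT, IN, YR
    orf: Interval
    frame: int
    score: float
    best_reference: str
    percent_identity: float

    def __post_init__(self) -> None:
        if self.name not in {"GAG", "PR", "RT", "IN", "YR"}:
            raise ValidationError(f"unknown domain name {self.name!r}")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValidationError("percent_identity must lie in [0, 100]")
        if self.frame not in {1, 2, 3, -1, -2, -3}:
            raise ValidationError(f"invalid frame {self.frame}")


@dataclass
class ElementAnnotation:
    """One intact LTR retroelement.

    ``body`` spans the outermost LTR bounds (TSDs excluded).  ``flank_motif``
    is one of "TGT/ACA", "TG/CA", "other", "absent"; ``tsd`` is the duplicated
    flanking word (4-6 bp) or None.  ``ltr_seq`` caches the 5' LTR residues so
    family clustering does not need the genome in hand.
    """

    id: Optional[str]
    group: Group
    family: Optional[str]
    ltr5: Interval
    ltr3: Interval
    body: Interval
    ltr_similarity: float
    flank_motif: str
    tsd: Optional[str]
    domains: list[DomainHit] = field(default_factory=list)
    repeat_mode: RepeatMode = RepeatMode.DIRECT
    ltr_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ltr5.end > self.ltr3.start:
            raise ValidationError("5' LTR must end before the 3' LTR starts")
        if (self.body.start, self.body.end) != (self.ltr5.start, self.ltr3.end):
            raise ValidationError("body must span the outermost LTR bounds")
        if not (0.0 <= self.ltr_similarity <= 100.0):
            raise ValidationError("ltr_similarity must lie in [0, 100]")
        if self.tsd is not None and len(self.tsd) not in (4, 5, 6):
            raise ValidationError("TSD length must be 4-6 bp when present")
        if (self.group is Group.DIRS) != (self.repeat_mode is RepeatMode.INVERTED):
            raise ValidationError("repeat_mode is inverted iff group is DIRS")
        if self.flank_motif not in {"TGT/ACA", "TG/CA", "other", "absent"}:
            raise ValidationError(f"unknown flank motif {self.flank_motif!r}")

    @property
    def length(self) -> int:
        return len(self.body)

    def domain(self, name: str) -> Optional[DomainHit]:
        """Best hit for a domain name, or None."""
        hits = [d for d in self.domains if d.name == name]
        return max(hits, key=lambda d: d.score) if hits else None

    def with_identity(self, id: str, family: str, group: Group) -> "ElementAnnotation":
        mode = RepeatMode.INVERTED if group is Group.DIRS else RepeatMode.DIRECT
        return replace(self, id=id, family=family, group=group, repeat_mode=mode)
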